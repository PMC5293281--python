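"""Core data model and I/O for the DCE-MRI radiomics pipeline.

A case is a triple of 3D volumes acquired before (S-0) and after (S-1, S-2)
contrast injection, together with breast and tumor masks, two clinical
covariates (age, menopausal status) and a molecular-subtype label.

Coordinate convention: voxel indices are 0-based ``(x, y, z)`` triples with
x = left-right, y = anterior-posterior (the chest wall bounds the posterior
extent, i.e. large y), z = slice. All masks share the volume grid.

Volumes are stored on disk as NIfTI (.nii / .nii.gz); feature tables as CSV
with a header row and the subtype label in the last column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

SUBTYPES = ("luminalA", "luminalB", "HER2", "basal")

N_FEATURES = 90

#: (name, length) of the consecutive feature blocks; lengths sum to 90.
FEATURE_BLOCKS = (
    ("clinical", 2),
    ("tumor_first_order", 15),
    ("morphologic", 5),
    ("tumor_texture", 15),
    ("tumor_dynamic", 11),
    ("bpe_texture", 15),
    ("bpe_dynamic", 18),
    ("bilateral", 9),
)


class VolumeIOError(Exception):
    """Base class for volume reading/writing failures."""


class MissingVolumeError(VolumeIOError):
    """The requested volume file does not exist."""


class UnreadableVolumeError(VolumeIOError):
    """The file exists but its header or payload cannot be parsed."""


class NotA3DVolumeError(VolumeIOError):
    """The file parses but does not hold a 3D scalar payload."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with physical voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise NotA3DVolumeError(f"expected a 3D grid, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BreastMask:
    """Left/right breast compartments, chest wall excluded from both.

    ``laterality_of_lesion`` is "left" or "right" once a lesion has been
    located (``None`` for a freshly segmented, lesion-agnostic mask).
    """

    left: np.ndarray
    right: np.ndarray
    laterality_of_lesion: str | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=bool)
        self.right = np.asarray(self.right, dtype=bool)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right masks must share one grid")
        if np.any(self.left & self.right):
            raise ValueError("left and right breast masks must be disjoint")
        if self.laterality_of_lesion not in (None, "left", "right"):
            raise ValueError(f"bad laterality {self.laterality_of_lesion!r}")

    @property
    def lesion_side(self) -> np.ndarray:
        if self.laterality_of_lesion is None:
            raise ValueError("laterality of lesion not set")
        return self.left if self.laterality_of_lesion == "left" else self.right

    @property
    def contralateral_side(self) -> np.ndarray:
        if self.laterality_of_lesion is None:
            raise ValueError("laterality of lesion not set")
        return self.right if self.laterality_of_lesion == "left" else self.left

    def union(self) -> np.ndarray:
        return self.left | self.right


@dataclass
class TumorMask:
    """Binary tumor mask plus the seed voxel it was grown from."""

    mask: np.ndarray
    seed: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.seed = tuple(int(c) for c in self.seed)
        if not self.mask.any():
            raise ValueError("tumor mask is empty")
        if not self.mask[self.seed]:
            raise ValueError("seed voxel is outside the tumor mask")


@dataclass
class DceCase:
    """One subject: S-0/S-1/S-2 series, masks, clinical covariates, label.

    ``menopausal`` is coded 0 = premenopausal, 1 = postmenopausal.
    Masks may be ``None`` before the segmentation stage has run.
    """

    case_id: str
    series: tuple[Volume, Volume, Volume]
    age: float
    menopausal: int
    subtype: str
    breast_mask: BreastMask | None = None
    tumor_mask: TumorMask | None = None

    def __post_init__(self) -> None:
        if len(self.series) != 3:
            raise ValueError("a case holds exactly three series (S-0, S-1, S-2)")
        s0 = self.series[0]
        for v in self.series[1:]:
            if v.shape != s0.shape or v.spacing != s0.spacing:
                raise ValueError("all series must share one grid shape and spacing")
        if self.age is None or self.menopausal is None:
            raise ValueError("clinical covariates (age, menopausal) are required")
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if int(self.menopausal) not in (0, 1):
            raise ValueError("menopausal must be 0 (pre) or 1 (post)")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")

    @property
    def s0(self) -> Volume:
        return self.series[0]

    @property
    def s1(self) -> Volume:
        return self.series[1]

    @property
    def s2(self) -> Volume:
        return self.series[2]


def feature_schema() -> dict[int, str]:
    """The fixed 1-based index -> name registry of the 90-feature vector.

    Block layout (indices): 1-2 clinical, 3-17 tumor first-order,
    18-22 morphologic, 23-37 tumor texture, 38-48 tumor dynamic,
    49-63 BPE texture, 64-81 BPE dynamic, 82-90 bilateral difference.
    Within a block the order is image-major (S-0, S-1, S-2) then statistic.
    """
    images = ("s0", "s1", "s2")
    first_order = ("skewness", "kurtosis", "max", "mean", "sd")
    glcm = ("contrast", "correlation", "energy", "homogeneity", "entropy")
    maps = ("sub10", "sub20", "sub21")
    dyn_stats = ("mean", "sd", "max")

    names: list[str] = ["age", "menopausal_status"]
    names += [f"tumor_{img}_{st}" for img in images for st in first_order]
    names += [
        "tumor_volume_mm3",
        "tumor_diameter_mm",
        "tumor_radius_sd_mm",
        "tumor_roughness",
        "tumor_compactness",
    ]
    names += [f"tumor_{img}_glcm_{st}" for img in images for st in glcm]
    names += [f"tumor_{m}_{st}" for m in maps for st in dyn_stats]
    names += ["tumor_ratio_sub20_sub10_mean", "tumor_ratio_sub21_sub10_mean"]
    names += [f"bpe_{img}_glcm_{st}" for img in images for st in glcm]
    names += [f"bpe_{side}_{m}_{st}" for side in ("lesion", "contra") for m in maps for st in dyn_stats]
    names += [f"bilateral_{m}_{st}" for m in maps for st in dyn_stats]
    assert len(names) == N_FEATURES
    return {i + 1: name for i, name in enumerate(names)}


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 90-value feature record of one case."""

    values: np.ndarray
    schema: Mapping[int, str] = field(default_factory=feature_schema)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have exactly {N_FEATURES} values")
        if not np.all(np.isfinite(vals)):
            bad = [self.schema[i + 1] for i in np.flatnonzero(~np.isfinite(vals))]
            raise ValueError(f"non-finite feature values: {bad}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, index: int) -> float:
        """1-based access matching the schema indices."""
        if not 1 <= index <= N_FEATURES:
            raise IndexError(index)
        return float(self.values[index - 1])


@dataclass
class FeatureTable:
    """Per-case feature vectors with subtype labels and case ids."""

    rows: list[FeatureVector]
    labels: list[str]
    case_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.labels):
            raise ValueError("one label per row required")
        if self.case_ids is None:
            self.case_ids = [f"case{i:03d}" for i in range(len(self.rows))]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([r.values for r in self.rows]) if self.rows else np.empty((0, N_FEATURES))

    def to_frame(self) -> pd.DataFrame:
        schema = feature_schema()
        cols = [schema[i] for i in range(1, N_FEATURES + 1)]
        df = pd.DataFrame(self.matrix, columns=cols, index=pd.Index(self.case_ids, name="case_id"))
        df["subtype"] = self.labels
        return df


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing is taken from the file header."""
    path = Path(path)
    if not path.exists():
        raise MissingVolumeError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
    except MissingVolumeError:
        raise
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise UnreadableVolumeError(f"cannot read {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise NotA3DVolumeError(f"{path} is not a 3D volume (payload ndim={data.ndim})")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=tuple(float(z) for z in zooms[:3]), origin=origin)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI with spacing in the header."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(Path(path)))


def write_mask(mask: np.ndarray, spacing: Sequence[float], path: str | Path) -> None:
    write_volume(Volume(np.asarray(mask, dtype=np.float64), tuple(spacing)), path)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV: header row, one row per case, label last.

    Floats are written with shortest-round-trip repr so that reading the file
    back reproduces the table bit-exactly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    schema = feature_schema()
    header = ["case_id"] + [schema[i] for i in range(1, N_FEATURES + 1)] + ["subtype"]
    lines = [",".join(header)]
    for cid, row, label in zip(table.case_ids, table.rows, table.labels):
        # repr(float) is the shortest representation that round-trips exactly
        lines.append(",".join([str(cid)] + [repr(float(v)) for v in row.values] + [str(label)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(Path(path), index_col="case_id", float_precision="round_trip")
    labels = df.pop("subtype").tolist()
    rows = [FeatureVector(df.iloc[i].to_numpy(dtype=np.float64)) for i in range(len(df))]
    return FeatureTable(rows=rows, labels=labels, case_ids=[str(c) for c in df.index])


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one flat record.

    Every value can be overridden from a YAML/JSON file via :func:`load_config`.
    """

    # synthetic phantom
    grid_shape: tuple[int, int, int] = (96, 96, 24)
    voxel_spacing: tuple[float, float, float] = (0.625, 0.625, 1.2)
    max_planted_shift: int = 3

    # segmentation
    fcm_classes: int = 2
    fcm_fuzzifier: float = 2.0
    fcm_alpha: float = 0.5
    fcm_tol: float = 1e-4
    fcm_max_iter: int = 100
    mrf_beta: float = 1.0
    mrf_max_iter: int = 10
    mrf_neighborhood: int = 6
    tumor_input: str = "subtraction"  # "subtraction" (S-1 - S-0) or "s1"
    min_centroid_gap_frac: float = 0.15  # x mean breast S-0 intensity

    # registration
    reg_window: int = 32
    reg_radius: int = 10

    # features
    glcm_levels: int = 32
    bpe_percent: float = 1.0
    rel_epsilon_frac: float = 1e-6  # x mean S-0, floor for relative enhancement
    ratio_epsilon_frac: float = 1e-6  # x mean S-0, guard for subtraction ratios

    # evolutionary search
    ea_population: int = 500
    ea_generations: int = 200
    ea_p_mutation: float = 0.01
    ea_p_crossover: float = 0.6
    ea_fitness_folds: int = 5
    ea_fitness_mode: str = "cv"  # "cv" (out-of-fold AUC) or "train"
    ea_stagnation: int = 20

    # cross-validation / classifier
    cv_inner_folds: int = 5
    wrapper_min_improvement: float = 1e-4
    ridge: float = 1e-8

    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON, applying keyword overrides."""
    d: dict = {}
    if path is not None:
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else (yaml.safe_load(text) or {})
    d.update(overrides)
    return PipelineConfig.from_dict(d)
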