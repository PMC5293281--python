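"""Synthetic bilateral-breast DCE-MRI phantoms with known ground truth.

Each phantom holds two breast half-ellipsoids attached to a bright
chest-wall/body slab at the posterior edge of the grid, with spatially
correlated (log-normal) fibroglandular texture, an ellipsoidal lobulated
tumor in one breast, subtype-dependent contrast kinetics and background
parenchymal enhancement (BPE), additive Gaussian sensor noise, and known
integer in-plane translations applied to the postcontrast series S-1 and
S-2. Ground truth (tumor mask, breast compartments, shifts, kinetic
parameters) is returned alongside every case, so segmentation, registration,
feature extraction and classification are all testable without real data.

The subtype presets encode the qualitative contrasts the pipeline is
expected to recover: luminal A tumors have low intensity skewness/kurtosis
while luminal B tumors are heterogeneous and right-skewed, and HER2 cases
show the strongest parenchymal enhancement in the contralateral (normal)
breast. They are test fixtures, not claims about biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import SUBTYPES, BreastMask, DceCase, FeatureTable, FeatureVector, TumorMask, Volume

DEFAULT_GRID = (96, 96, 24)
DEFAULT_SPACING = (0.625, 0.625, 1.2)

#: fraction of the anterior-posterior extent in front of the chest wall
_WALL_FRACTION = 0.78
_BASE_INTENSITY = 300.0
_WALL_INTENSITY = 650.0
_TEXTURE_SIGMA = 0.22
DEFAULT_NOISE_SIGMA = 8.0


@dataclass(frozen=True)
class SubtypeKinetics:
    """Per-subtype enhancement parameters (unitless multipliers of baseline)."""

    subtype: str
    tumor_uptake: tuple[float, float]  # fractional enhancement multiplier at S-1, S-2
    tumor_heterogeneity: float  # within-tumor enhancement dispersion
    intensity_skew: float  # target asymmetry of the tumor enhancement histogram
    bpe_level_lesion_side: float  # fractional parenchymal enhancement
    bpe_level_contralateral: float

    def __post_init__(self) -> None:
        if any(u < 0 for u in self.tumor_uptake) or self.tumor_heterogeneity < 0:
            raise ValueError("enhancement multipliers and dispersion must be >= 0")


KINETIC_PRESETS: dict[str, SubtypeKinetics] = {
    # luminal A: homogeneous, near-symmetric tumor enhancement; low BPE
    "luminalA": SubtypeKinetics("luminalA", (1.6, 1.8), 0.06, 0.2, 0.10, 0.08),
    # luminal B: heterogeneous, right-skewed tumor enhancement; low BPE
    "luminalB": SubtypeKinetics("luminalB", (1.8, 1.9), 0.30, 1.8, 0.10, 0.08),
    # HER2: strongest enhancement overall and highest BPE in the normal breast
    "HER2": SubtypeKinetics("HER2", (2.0, 2.3), 0.15, 0.8, 0.30, 0.30),
    # basal-like: strong enhancement, intermediate BPE
    "basal": SubtypeKinetics("basal", (1.9, 2.1), 0.15, 0.8, 0.14, 0.12),
}


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    tumor_mask: np.ndarray
    shifts: dict[str, tuple[int, int]]  # in-plane (dx, dy) applied to S-1, S-2
    kinetics: SubtypeKinetics
    rng_seed: int
    breast_left: np.ndarray = field(default=None, repr=False)
    breast_right: np.ndarray = field(default=None, repr=False)
    laterality: str = "left"


def _smooth_field(rng: np.random.Generator, shape, sigma=(3.0, 3.0, 1.5)) -> np.ndarray:
    """Zero-mean unit-variance spatially correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / max(f.std(), 1e-12)

def _breast_compartments(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, int]:
    nx, ny, nz = shape
    y_wall = int(round(_WALL_FRACTION * ny))
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cz = (nz - 1) / 2.0
    ax, ay, az = 0.21 * nx, 0.62 * y_wall, 0.46 * nz

    def half_ellipsoid(cx: float) -> np.ndarray:
        rho = ((x - cx) / ax) ** 2 + ((y - y_wall) / ay) ** 2 + ((z - cz) / az) ** 2
        return (rho <= 1.0) & (y < y_wall)

    left = half_ellipsoid(0.27 * nx)
    right = half_ellipsoid(0.73 * nx)
    return left, right, y_wall


def _lobulated_tumor(rng: np.random.Generator, shape, center, radii, lobulation=0.18) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    rho = np.sqrt(
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    )
    bumps = _smooth_field(rng, shape, sigma=(1.5, 1.5, 1.0))
    mask = rho + lobulation * bumps <= 1.0
    # keep the single 26-connected component containing the center
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    lab = labels[tuple(center)]
    if lab == 0:  # lobulation carved out the center: fall back to the ellipsoid
        mask = rho <= 1.0
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        lab = labels[tuple(center)]
    return labels == lab


def _apply_shift(volume: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer in-plane translation with edge replication."""
    return ndimage.shift(volume, (dx, dy, 0), order=0, mode="nearest")


def generate_case(
    subtype: str,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    seed: int = 0,
    *,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    max_shift: int = 3,
    case_id: str | None = None,
) -> tuple[DceCase, SyntheticGroundTruth]:
    """Generate one phantom case with ground truth. Deterministic in ``seed``."""
    if subtype not in KINETIC_PRESETS:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    nx, ny, nz = grid_shape
    if nx < 32 or ny < 32 or nz < 8:
        raise ValueError(f"grid {grid_shape} too small for two breasts and a chest wall")
    kin = KINETIC_PRESETS[subtype]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD0E]))

    left, right, y_wall = _breast_compartments(grid_shape)
    breast = left | right

    # precontrast anatomy: textured parenchyma, bright chest-wall/body slab
    texture = np.exp(_TEXTURE_SIGMA * _smooth_field(rng, grid_shape, sigma=(2.0, 2.0, 1.0)))
    s0 = np.zeros(grid_shape)
    s0[breast] = _BASE_INTENSITY * texture[breast]
    s0[:, y_wall:, :] = _WALL_INTENSITY

    # tumor geometry in one breast
    laterality = "left" if rng.random() < 0.5 else "right"
    side = left if laterality == "left" else right
    cx = 0.27 * nx if laterality == "left" else 0.73 * nx
    center = (int(round(cx)), int(round(y_wall - 0.45 * 0.62 * y_wall)), nz // 2)
    radii = (
        rng.uniform(5.0, 7.5),
        rng.uniform(5.0, 7.5),
        rng.uniform(2.5, 4.0),
    )
    tumor = _lobulated_tumor(rng, grid_shape, center, radii) & side
    s0[tumor] = 1.1 * _BASE_INTENSITY * texture[tumor]

    # per-voxel tumor enhancement multipliers: skewed, heterogeneous
    n_t = int(tumor.sum())
    if kin.intensity_skew > 1e-6:
        k = (2.0 / kin.intensity_skew) ** 2
        g = (rng.gamma(k, 1.0, size=n_t) - k) / np.sqrt(k)
    else:
        g = rng.standard_normal(n_t)
    het = np.maximum(1.0 + kin.tumor_heterogeneity * g, 0.05)

    # BPE spatial pattern per breast, in [0, 1]
    bpe_pattern = _smooth_field(rng, grid_shape, sigma=(3.0, 3.0, 1.5))
    pat = np.zeros(grid_shape)
    for comp in (left, right):
        v = bpe_pattern[comp]
        lo, hi = v.min(), v.max()
        pat[comp] = (v - lo) / max(hi - lo, 1e-12)

    lesion_parenchyma = side & ~tumor
    contra = right if laterality == "left" else left

    series = [s0 + rng.normal(0.0, noise_sigma, grid_shape)]
    shifts: dict[str, tuple[int, int]] = {}
    ramps = (0.8, 1.0)
    for t, name in enumerate(("s1", "s2")):
        enh = np.ones(grid_shape)
        enh[lesion_parenchyma] = 1.0 + kin.bpe_level_lesion_side * ramps[t] * pat[lesion_parenchyma]
        enh[contra] = 1.0 + kin.bpe_level_contralateral * ramps[t] * pat[contra]
        enh[tumor] = 1.0 + (kin.tumor_uptake[t] - 1.0) * het
        st = s0 * enh + rng.normal(0.0, noise_sigma, grid_shape)
        dx, dy = (int(rng.integers(-max_shift, max_shift + 1)), int(rng.integers(-max_shift, max_shift + 1))) if max_shift > 0 else (0, 0)
        shifts[name] = (dx, dy)
        series.append(_apply_shift(st, dx, dy))

    age = float(rng.integers(29, 79))
    # menopause: probability rises with age around 50
    menopausal = int(rng.random() < 1.0 / (1.0 + np.exp(-(age - 50.0) / 3.0)))

    case = DceCase(
        case_id=case_id or f"{subtype}_{seed}",
        series=tuple(Volume(v, spacing) for v in series),
        age=age,
        menopausal=menopausal,
        subtype=subtype,
        breast_mask=BreastMask(left=left, right=right, laterality_of_lesion=laterality),
        tumor_mask=TumorMask(mask=tumor, seed=center),
    )
    truth = SyntheticGroundTruth(
        tumor_mask=tumor,
        shifts=shifts,
        kinetics=kin,
        rng_seed=int(seed),
        breast_left=left,
        breast_right=right,
        laterality=laterality,
    )
    return case, truth


def generate_cohort(
    n_per_subtype: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    seed: int = 0,
    **case_kwargs,
) -> tuple[list[DceCase], list[SyntheticGroundTruth]]:
    """4 x n_per_subtype cases with per-case seeds derived from ``seed``."""
    if n_per_subtype < 1:
        raise ValueError("n_per_subtype must be >= 1")
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(4 * n_per_subtype) % (2**31)
    cases: list[DceCase] = []
    truths: list[SyntheticGroundTruth] = []
    i = 0
    for subtype in SUBTYPES:
        for j in range(n_per_subtype):
            case, truth = generate_case(
                subtype,
                grid_shape,
                seed=int(child_seeds[i]),
                case_id=f"{subtype}_{j:02d}",
                **case_kwargs,
            )
            cases.append(case)
            truths.append(truth)
            i += 1
    return cases, truths


def planted_feature_table(
    n_per_class: int = 15,
    informative: tuple[int, ...] = (3, 40, 83),
    effect: float = 1.2,
    seed: int = 0,
) -> FeatureTable:
    """A 90-feature table where only ``informative`` (1-based) indices carry
    class signal: each gets a +/- ``effect`` offset pattern over the four
    subtypes (sign patterns chosen so the classes sit at distinct corners);
    all other features are N(0, 1) noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
    patterns = ([1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1])
    n = 4 * n_per_class
    X = rng.standard_normal((n, 90))
    labels = [s for s in SUBTYPES for _ in range(n_per_class)]
    for k, fidx in enumerate(informative):
        pat = patterns[k % len(patterns)]
        for ci in range(4):
            rows = slice(ci * n_per_class, (ci + 1) * n_per_class)
            X[rows, fidx - 1] += effect * pat[ci]
    rows = [FeatureVector(X[i]) for i in range(n)]
    return FeatureTable(rows=rows, labels=labels)
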