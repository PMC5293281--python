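"""Extraction of the 90-element radiomic feature vector.

From a registered, segmented case the extractor computes 88 imaging
features — tumor first-order statistics, morphology, 3D gray-level
co-occurrence (GLCM) texture, kinetic (subtraction-map) features of the
tumor, texture and kinetic features of the background parenchymal
enhancement (BPE) in both breasts, and bilateral BPE differences — and
prepends the two clinical covariates (age, menopausal status).

Feature order (1-based indices): 1-2 clinical; 3-17 tumor first-order
(S-0, S-1, S-2 x skewness, kurtosis, max, mean, sd); 18-22 morphologic;
23-37 tumor GLCM texture; 38-48 tumor dynamic; 49-63 BPE texture;
64-81 BPE dynamic (lesion side then contralateral); 82-90 bilateral
differences. See :func:`dceradiomics.core_io.feature_schema`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .core_io import BreastMask, DceCase, FeatureVector, PipelineConfig, TumorMask, Volume

log = logging.getLogger(__name__)

#: the 13 unique 3D unit-displacement offsets (half of the 26-neighborhood)
UNIT_OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
)


@dataclass
class GlcmSpec:
    """Gray-level quantization and offset set for 3D co-occurrence analysis."""

    levels: int = 32
    offsets: tuple[tuple[int, int, int], ...] = UNIT_OFFSETS_3D
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if any(o == (0, 0, 0) for o in self.offsets):
            raise ValueError("offsets must be nonzero")


@dataclass
class EnhancementMaps:
    """Subtraction and relative-enhancement maps of a registered case.

    ``rel1``/``rel2`` hold (I_T - I_0) / I_0 where the baseline exceeds
    ``epsilon`` (``rel_valid`` marks those voxels) and 0 elsewhere.
    """

    sub10: np.ndarray
    sub20: np.ndarray
    sub21: np.ndarray
    rel1: np.ndarray
    rel2: np.ndarray
    rel_valid: np.ndarray
    epsilon: float


@dataclass
class BpeRegion:
    """Top-p% most-enhancing parenchymal voxels on one side."""

    side: str  # "lesion" or "contralateral"
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # index arrays
    p: float

    @property
    def count(self) -> int:
        return len(self.voxels[0])


def compute_enhancement_maps(case: DceCase, epsilon: float | None = None) -> EnhancementMaps:
    """Voxel-wise subtraction maps and relative enhancement (RTS) maps."""
    s0, s1, s2 = (v.data for v in case.series)
    if epsilon is None:
        epsilon = 1e-6 * float(np.abs(s0).mean())
    valid = s0 > epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        rel1 = np.where(valid, (s1 - s0) / s0, 0.0)
        rel2 = np.where(valid, (s2 - s0) / s0, 0.0)
    return EnhancementMaps(
        sub10=s1 - s0, sub20=s2 - s0, sub21=s2 - s1,
        rel1=rel1, rel2=rel2, rel_valid=valid, epsilon=float(epsilon),
    )


def first_order_features(volume: Volume | np.ndarray, mask: TumorMask | np.ndarray) -> tuple[float, float, float, float, float]:
    """(skewness, kurtosis, max, mean, sd) of the masked voxel intensities.

    Skewness and kurtosis are the third and fourth standardized central
    moments (kurtosis non-excess: a normal sample tends to 3); sd uses
    population (1/N) normalization. A constant region returns skewness 0 and
    kurtosis 0 by convention.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    vals = data[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = float(vals.mean())
    centered = vals - mean
    var = float((centered**2).mean())
    sd = math.sqrt(var)
    if sd == 0:
        return (0.0, 0.0, float(vals.max()), mean, 0.0)
    skew = float((centered**3).mean()) / sd**3
    kurt = float((centered**4).mean()) / sd**4
    return (skew, kurt, float(vals.max()), mean, sd)


def morphologic_features(mask: TumorMask | np.ndarray, spacing: tuple[float, float, float]) -> tuple[float, float, float, float, float]:
    """(volume mm^3, diameter mm, radius sd mm, roughness, compactness).

    Radial lengths are distances from each surface voxel (a masked voxel
    with at least one 6-neighbor outside) to the mask centroid, in mm.
    Diameter is twice the mean radial length; roughness is the mean absolute
    radial deviation over the mean radial length. Compactness is the
    dimensionless sphericity measure 36*pi*V^2 / A^3 (1 for a sphere), with
    A the triangulated mesh surface area of the mask.
    """
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    vol = float(m.sum()) * float(np.prod(spacing))

    idx = np.argwhere(m)
    centroid_mm = idx.mean(axis=0) * spacing

    # surface voxels: >=1 face-neighbor outside the mask
    padded = np.pad(m, 1)
    interior = np.ones_like(m, dtype=bool)
    for axis in range(3):
        for sign in (-1, 1):
            interior &= np.roll(padded, sign, axis=axis)[1:-1, 1:-1, 1:-1]
    surface = m & ~interior
    surf_idx = np.argwhere(surface) if surface.any() else idx
    radial = np.linalg.norm(surf_idx * spacing - centroid_mm, axis=1)
    mean_r = float(radial.mean())
    radius_sd = float(radial.std())
    diameter = 2.0 * mean_r
    roughness = float(np.abs(radial - mean_r).mean()) / mean_r if mean_r > 0 else 0.0

    if m.sum() == 1:
        # single voxel: degenerate mesh; treat as a box of one voxel
        area = 2.0 * (spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2])
    else:
        # anti-aliased indicator: meshing the raw binary mask overestimates
        # the area of a smooth shape by ~10% (staircase facets); a 1-voxel
        # Gaussian smoothing before marching cubes removes most of the bias
        f = ndimage.gaussian_filter(np.pad(m, 2).astype(np.float64), sigma=1.0)
        if f.max() <= 0.5:  # object too small to survive smoothing
            f = np.pad(m, 1).astype(np.float64)
        verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=tuple(spacing))
        area = float(mesh_surface_area(verts, faces))
    compactness = 36.0 * math.pi * vol**2 / area**3
    return (vol, diameter, radius_sd, roughness, compactness)


def glcm3d_features(
    volume: Volume | np.ndarray,
    region: np.ndarray,
    spec: GlcmSpec | None = None,
) -> tuple[float, float, float, float, float]:
    """(contrast, correlation, energy, homogeneity, entropy) of the region.

    Intensities are linearly quantized to ``spec.levels`` bins over the
    region's min-max range; co-occurrences are accumulated over all offsets
    for voxel pairs that both lie inside the region, symmetrized and
    normalized to sum 1. Haralick formulas with log base 2 for entropy.
    A region occupying a single gray level returns the degenerate
    single-cell-matrix values (0, 0, 1, 1, 0).
    """
    spec = spec or GlcmSpec()
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    vals = data[region]
    lo, hi = float(vals.min()), float(vals.max())
    L = spec.levels
    if hi > lo:
        q = np.minimum((data - lo) / (hi - lo) * L, L - 1).astype(np.int64)
        q = np.clip(q, 0, L - 1)
    else:
        q = np.zeros(data.shape, dtype=np.int64)

    counts = np.zeros((L, L), dtype=np.float64)
    shape = data.shape
    for off in spec.offsets:
        src = tuple(slice(max(-o, 0), shape[d] - max(o, 0)) for d, o in enumerate(off))
        dst = tuple(slice(max(o, 0), shape[d] + min(o, 0)) for d, o in enumerate(off))
        both = region[src] & region[dst]
        if not both.any():
            continue
        a = q[src][both]
        b = q[dst][both]
        np.add.at(counts, (a, b), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:  # no valid pair (e.g. single isolated voxel)
        return (0.0, 0.0, 1.0, 1.0, 0.0)
    p = counts / total

    i = np.arange(L, dtype=np.float64)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((i * pj).sum())
    sd_i = math.sqrt(float(((i - mu_i) ** 2 * pi).sum()))
    sd_j = math.sqrt(float(((i - mu_j) ** 2 * pj).sum()))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = float((p * (ii - mu_i) * (jj - mu_j)).sum()) / (sd_i * sd_j)
    else:
        correlation = 0.0
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return (contrast, correlation, energy, homogeneity, entropy)


def tumor_dynamic_features(maps: EnhancementMaps, mask: TumorMask | np.ndarray, ratio_epsilon: float | None = None) -> tuple[float, ...]:
    """11 kinetic features of the tumor: mean/sd/max of the three
    subtraction maps, plus the mean voxel-wise ratios (S2-S0)/(S1-S0) and
    (S2-S1)/(S1-S0) over voxels with ``|S1-S0| > ratio_epsilon``.
    Population-sd convention throughout.
    """
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    if ratio_epsilon is None:
        ratio_epsilon = 1e-6 * float(np.abs(maps.sub10).mean() + 1e-300)
    out: list[float] = []
    for sub in (maps.sub10, maps.sub20, maps.sub21):
        v = sub[m]
        out += [float(v.mean()), float(v.std()), float(v.max())]
    denom = maps.sub10[m]
    ok = np.abs(denom) > ratio_epsilon
    if ok.any():
        out.append(float((maps.sub20[m][ok] / denom[ok]).mean()))
        out.append(float((maps.sub21[m][ok] / denom[ok]).mean()))
    else:
        log.warning("no tumor voxel with |S1-S0| above epsilon; ratio features set to 0")
        out += [0.0, 0.0]
    return tuple(out)


def bpe_select(
    maps: EnhancementMaps,
    breast_mask: BreastMask,
    tumor_mask: TumorMask | np.ndarray,
    side: str,
    p: float = 1.0,
) -> BpeRegion:
    """Top-``p``% parenchymal voxels by relative enhancement at S-1.

    Eligible voxels are the chosen side's breast compartment minus the tumor;
    they are ranked by ``rel1`` descending, ties broken by flat voxel index
    ascending, and the top ``ceil(p% * n_eligible)`` (at least 1) selected.
    """
    if side not in ("lesion", "contralateral"):
        raise ValueError(f"side must be 'lesion' or 'contralateral', got {side!r}")
    tmask = tumor_mask.mask if isinstance(tumor_mask, TumorMask) else np.asarray(tumor_mask, dtype=bool)
    compartment = breast_mask.lesion_side if side == "lesion" else breast_mask.contralateral_side
    eligible = compartment & ~tmask
    n = int(eligible.sum())
    if n == 0:
        raise ValueError(f"no eligible parenchymal voxels on the {side} side")
    flat = np.flatnonzero(eligible.ravel())
    rel = maps.rel1.ravel()[flat]
    k = max(1, math.ceil(p / 100.0 * n))
    order = np.lexsort((flat, -rel))  # rel descending, then voxel index ascending
    chosen = flat[order[:k]]
    voxels = np.unravel_index(np.sort(chosen), eligible.shape)
    return BpeRegion(side=side, voxels=voxels, p=p)


def bpe_features(
    case: DceCase,
    maps: EnhancementMaps,
    lesion_region: BpeRegion,
    contra_region: BpeRegion,
    spec: GlcmSpec | None = None,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """BPE texture (15) and dynamic (18) feature blocks.

    Texture: GLCM features of the lesion-side parenchyma (breast minus
    tumor) on S-0, S-1 and S-2. Dynamic: mean/sd/max of each subtraction map
    over the top-p% BPE voxels, lesion side first, then contralateral.
    """
    if lesion_region.count == 0 or contra_region.count == 0:
        raise ValueError("empty BPE region")
    parenchyma = case.breast_mask.lesion_side & ~case.tumor_mask.mask
    texture: list[float] = []
    for vol in case.series:
        texture += list(glcm3d_features(vol, parenchyma, spec))

    dynamic: list[float] = []
    for region in (lesion_region, contra_region):
        for sub in (maps.sub10, maps.sub20, maps.sub21):
            v = sub[region.voxels]
            dynamic += [float(v.mean()), float(v.std()), float(v.max())]
    return tuple(texture), tuple(dynamic)


def bilateral_difference(bpe_dynamic: tuple[float, ...]) -> tuple[float, ...]:
    """Lesion-side minus contralateral value for each of the 9 (map x
    statistic) BPE kinetic features."""
    if len(bpe_dynamic) != 18:
        raise ValueError("expected the 18 BPE dynamic values")
    arr = np.asarray(bpe_dynamic, dtype=np.float64)
    return tuple(arr[:9] - arr[9:])


def extract_features(case: DceCase, config: PipelineConfig | None = None) -> FeatureVector:
    """Assemble the full 90-element feature vector of a registered,
    segmented case. Deterministic given the case and configuration."""
    cfg = config or PipelineConfig()
    if case.breast_mask is None or case.tumor_mask is None:
        raise ValueError("case must be segmented (breast and tumor masks) before extraction")
    if case.breast_mask.laterality_of_lesion is None:
        raise ValueError("lesion laterality must be set on the breast mask")
    spec = GlcmSpec(levels=cfg.glcm_levels)
    s0_scale = float(np.abs(case.s0.data).mean())
    maps = compute_enhancement_maps(case, epsilon=cfg.rel_epsilon_frac * s0_scale)

    values: list[float] = [float(case.age), float(case.menopausal)]
    for vol in case.series:
        values += list(first_order_features(vol, case.tumor_mask))
    values += list(morphologic_features(case.tumor_mask, case.s0.spacing))
    for vol in case.series:
        values += list(glcm3d_features(vol, case.tumor_mask.mask, spec))
    values += list(tumor_dynamic_features(maps, case.tumor_mask, ratio_epsilon=cfg.ratio_epsilon_frac * s0_scale))

    lesion_region = bpe_select(maps, case.breast_mask, case.tumor_mask, "lesion", cfg.bpe_percent)
    contra_region = bpe_select(maps, case.breast_mask, case.tumor_mask, "contralateral", cfg.bpe_percent)
    texture, dynamic = bpe_features(case, maps, lesion_region, contra_region, spec)
    values += list(texture)
    values += list(dynamic)
    values += list(bilateral_difference(dynamic))
    return FeatureVector(np.asarray(values))
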