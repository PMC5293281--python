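"""Breast-region and tumor segmentation.

Breast region: the S-0 volume is thresholded into tissue vs air (Otsu), the
chest wall is detected as the anterior boundary of the rearmost
high-intensity slab per sagittal column (median-smoothed across columns),
voxels at or behind it are excluded, and the remaining tissue is split at
the x midline into left and right compartments. The chest-wall heuristic is
phantom-grade; real pectoral-muscle delineation is harder and out of scope.

Tumor: from a radiologist-style seed voxel, a two-class spatial fuzzy
C-means (FCM) partition of the enhancement map (S-1 minus S-0) on the seed
slice is refined by an Ising-prior Markov-random-field pass (iterated
conditional modes with Gaussian class likelihoods), then propagated to
adjacent slices, warm-starting each slice with the previous slice's
component and re-estimating the likelihood parameters from it — the
"adaptive" cross-slice coupling. The final mask is the 26-connected
component containing the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .core_io import BreastMask, DceCase, PipelineConfig, TumorMask, Volume

log = logging.getLogger(__name__)


class EmptyForegroundError(Exception):
    """Thresholding left no tissue voxels."""


class SeedOutsideBreastError(Exception):
    """The tumor seed does not fall inside either breast compartment."""


class NoEnhancingLesionError(Exception):
    """No enhancing component at the seed (e.g. seed in a tumor-free breast)."""


@dataclass
class FcmResult:
    """Per-voxel fuzzy memberships and ascending class centroids."""

    memberships: np.ndarray  # (n_voxels, c), rows sum to 1
    centroids: np.ndarray  # (c,), sorted ascending
    converged: bool
    n_iter: int


@dataclass
class MrfParams:
    """Ising-prior smoothing parameters for the ICM refinement pass."""

    beta: float = 1.0  # pairwise smoothness weight
    max_iterations: int = 10
    neighborhood: int = 6  # 6 or 26 connectivity

    def __post_init__(self) -> None:
        if self.beta < 0 or self.max_iterations < 1:
            raise ValueError("beta must be >= 0 and max_iterations >= 1")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")


# ---------------------------------------------------------------------------
# Breast-region segmentation


def segment_breast(volume: Volume) -> BreastMask:
    """Threshold tissue, cut at the detected chest wall, split at the midline."""
    data = volume.data
    finite_range = data.max() - data.min()
    if finite_range <= 0:
        raise EmptyForegroundError("volume is constant; no foreground after thresholding")
    # three intensity populations: air, parenchyma, chest wall/body
    try:
        tissue_thresh, wall_thresh = threshold_multiotsu(data, classes=3)
    except ValueError:  # fewer distinct gray levels than classes
        tissue_thresh, wall_thresh = threshold_otsu(data), np.inf
    foreground = data > tissue_thresh
    if not foreground.any():
        raise EmptyForegroundError("no voxels above the tissue threshold")
    wall = data > wall_thresh

    nx, ny, nz = data.shape
    # per sagittal column (x, z): anterior edge of the posterior wall run
    boundary = np.full((nx, nz), ny, dtype=int)
    wall_cols = wall.transpose(0, 2, 1)  # (x, z, y)
    posterior_runs = np.cumsum(wall_cols[:, :, ::-1], axis=2)  # run length from the back
    contiguous = posterior_runs == np.arange(1, ny + 1)
    run_len = contiguous.sum(axis=2)
    has_wall = run_len > 0
    boundary[has_wall] = ny - run_len[has_wall]
    boundary = ndimage.median_filter(boundary, size=5, mode="nearest")

    yy = np.arange(ny)[None, :, None]
    anterior = yy < boundary[:, None, :]
    breast = foreground & anterior
    if not breast.any():
        raise EmptyForegroundError("no tissue anterior to the chest wall")

    mid = nx // 2
    left = breast.copy()
    left[mid:, :, :] = False
    right = breast.copy()
    right[:mid, :, :] = False
    return BreastMask(left=left, right=right)


# ---------------------------------------------------------------------------
# Spatial fuzzy C-means


def _fcm_memberships(values: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))."""
    d = np.abs(values[:, None] - centroids[None, :])
    d = np.maximum(d, 1e-12)
    p = 2.0 / (m - 1.0)
    inv = d ** (-p)
    return inv / inv.sum(axis=1, keepdims=True)


def spatial_fcm(
    values: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray] | None = None,
    shape: tuple[int, int] | None = None,
    c: int = 2,
    m: float = 2.0,
    alpha: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
    init_centroids: np.ndarray | None = None,
) -> FcmResult:
    """Spatial fuzzy C-means on a masked 2D region.

    ``values`` are the region's intensities; ``coords`` their (row, col)
    positions on a grid of ``shape``. Each iteration blends the
    intensity-driven FCM membership with the mean membership of the in-plane
    8-neighborhood (weight ``alpha``) before re-normalizing. ``alpha = 0``
    reduces to textbook FCM. Non-convergence at the cap returns a flagged
    result rather than raising.

    ``init_centroids`` seeds the alternating optimization; the default
    (intensity quantiles) is adequate for balanced classes, but a small
    bright lesion against a large background needs an informed start (e.g.
    the enhancement at a seed voxel) to avoid a local optimum that splits
    the background instead.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if c < 2:
        raise ValueError("need at least 2 classes")
    if np.unique(values).size < c:
        raise ValueError(f"region has fewer than {c} distinct intensity values")
    if alpha > 0 and (coords is None or shape is None):
        raise ValueError("spatial blending (alpha > 0) needs coords and shape")

    # neighbor averaging via a dense membership image per class
    if alpha > 0:
        grid_idx = np.full(shape, -1, dtype=int)
        grid_idx[coords] = np.arange(values.size)
        kernel = np.ones((3, 3))
        kernel[1, 1] = 0.0
        inside = (grid_idx >= 0).astype(np.float64)
        neigh_count = ndimage.convolve(inside, kernel, mode="constant")

    if init_centroids is not None:
        centroids = np.asarray(init_centroids, dtype=np.float64).copy()
        if centroids.shape != (c,):
            raise ValueError(f"init_centroids must have shape ({c},)")
    else:
        # spread over the intensity range by quantiles
        centroids = np.quantile(values, np.linspace(0.05, 0.95, c))
    centroids = centroids + 1e-9 * np.arange(c)  # break exact ties
    u = _fcm_memberships(values, centroids, m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centroids = (um * values[:, None]).sum(axis=0) / np.maximum(um.sum(axis=0), 1e-300)
        u_new = _fcm_memberships(values, centroids, m)
        if alpha > 0:
            blended = np.empty_like(u_new)
            for k in range(c):
                img = np.zeros(shape)
                img[coords] = u_new[:, k]
                s = ndimage.convolve(img * inside, kernel, mode="constant")
                h = s[coords] / np.maximum(neigh_count[coords], 1.0)
                blended[:, k] = (1.0 - alpha) * u_new[:, k] + alpha * h
            u_new = blended / blended.sum(axis=1, keepdims=True)
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("spatial_fcm hit the iteration cap (%d) without converging", max_iter)
    order = np.argsort(centroids)
    return FcmResult(memberships=u[:, order], centroids=centroids[order], converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# MRF refinement (binary ICM with Gaussian likelihoods)


_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _gaussian_neg_loglik(data: np.ndarray, mean: float, var: float) -> np.ndarray:
    return 0.5 * (data - mean) ** 2 / var + 0.5 * np.log(2.0 * np.pi * var)


def _neighbor_label_counts(labels: np.ndarray, offsets) -> tuple[np.ndarray, np.ndarray]:
    """(count of neighbors labeled 1, count of valid neighbors) per voxel."""
    ones = np.zeros(labels.shape)
    total = np.zeros(labels.shape)
    lab = labels.astype(np.float64)
    for off in offsets:
        shifted = np.full(labels.shape, np.nan)
        src = tuple(slice(max(-o, 0), labels.shape[d] - max(o, 0)) for d, o in enumerate(off))
        dst = tuple(slice(max(o, 0), labels.shape[d] + min(o, 0)) for d, o in enumerate(off))
        shifted[dst] = lab[src]
        valid = ~np.isnan(shifted)
        ones[valid] += shifted[valid]
        total += valid
    return ones, total


def mrf_energy(labels: np.ndarray, data: np.ndarray, stats, beta: float, offsets) -> float:
    """Total energy: Gaussian negative log-likelihood minus beta x #agreeing pairs."""
    (m0, v0), (m1, v1) = stats
    nll = np.where(labels == 1, _gaussian_neg_loglik(data, m1, v1), _gaussian_neg_loglik(data, m0, v0))
    ones, total = _neighbor_label_counts(labels, offsets)
    agree = np.where(labels == 1, ones, total - ones)
    return float(nll.sum() - 0.5 * beta * agree.sum())  # each pair counted twice


def _class_stats(data: np.ndarray, labels: np.ndarray, min_var: float) -> list[tuple[float, float]] | None:
    stats = []
    for lab in (0, 1):
        sel = labels == lab
        if sel.sum() < 2:
            return None
        stats.append((float(data[sel].mean()), max(float(data[sel].var()), min_var)))
    return stats


def _pooled_stats(data: np.ndarray, labels: np.ndarray, min_var: float) -> list[tuple[float, float]] | None:
    """Class means with one shared variance.

    With per-class variances a broad tumor class can claim moderately
    enhancing parenchyma that is an outlier under a tight background class;
    pooling puts the likelihood boundary near the midpoint of the means.
    """
    stats = _class_stats(data, labels, min_var)
    if stats is None:
        return None
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    pooled = (n0 * stats[0][1] + n1 * stats[1][1]) / (n0 + n1)
    return [(stats[0][0], pooled), (stats[1][0], pooled)]


def mrf_refine(
    initial_labels: np.ndarray,
    volume: Volume | np.ndarray,
    params: MrfParams | None = None,
    class_stats: list[tuple[float, float]] | None = None,
    return_energies: bool = False,
):
    """Binary ICM on an Ising-prior energy; energy is non-increasing per sweep.

    Class likelihoods are Gaussian, estimated from ``initial_labels`` unless
    ``class_stats`` [(mean, var) for class 0, class 1] is supplied (used for
    the adaptive cross-slice propagation). Degenerate statistics (an empty
    class) return the initial labels unchanged with a logged warning.

    Voxels are updated in 8 parity phases (one per (x%2, y%2, z%2) triple), so
    no two simultaneously updated voxels are 26-neighbors and every phase
    update can only lower the energy.
    """
    params = params or MrfParams()
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    labels = np.asarray(initial_labels).astype(np.int8)
    if labels.shape != data.shape:
        raise ValueError("labels and volume must share one grid")
    if not labels.any():
        raise ValueError("initial labels are empty")
    offsets = _OFFSETS_6 if params.neighborhood == 6 else _OFFSETS_26

    min_var = max(1e-6, 1e-6 * float(np.var(data)))
    stats = class_stats if class_stats is not None else _class_stats(data, labels, min_var)
    if stats is None:
        log.warning("degenerate class statistics (one class empty); returning initial labels")
        return (labels.copy(), [mrf_energy(labels, data, [(0, 1), (0, 1)], 0.0, offsets)]) if return_energies else labels.copy()
    (m0, v0), (m1, v1) = stats
    nll0 = _gaussian_neg_loglik(data, m0, v0)
    nll1 = _gaussian_neg_loglik(data, m1, v1)

    idx = np.indices(data.shape)
    phases = [
        (idx[0] % 2 == px) & (idx[1] % 2 == py) & ((idx[2] % 2 == pz) if data.ndim == 3 else True)
        for px in (0, 1)
        for py in (0, 1)
        for pz in (0, 1)
    ]
    energies = [mrf_energy(labels, data, stats, params.beta, offsets)]
    for _ in range(params.max_iterations):
        changed = False
        for phase in phases:
            if not phase.any():
                continue
            ones, total = _neighbor_label_counts(labels, offsets)
            # local posterior energy for each label choice
            e0 = nll0 - params.beta * (total - ones)
            e1 = nll1 - params.beta * ones
            new = (e1 < e0).astype(np.int8)
            upd = phase & (new != labels)
            if upd.any():
                labels[upd] = new[upd]
                changed = True
        energies.append(mrf_energy(labels, data, stats, params.beta, offsets))
        if not changed:
            break
    return (labels, energies) if return_energies else labels


# ---------------------------------------------------------------------------
# Seed-based tumor segmentation


def _seed_side(breast: BreastMask, seed: tuple[int, int, int]) -> str:
    if breast.left[seed]:
        return "left"
    if breast.right[seed]:
        return "right"
    raise SeedOutsideBreastError(f"seed {seed} is outside both breast compartments")


def _slice_component(labels2d: np.ndarray, seed_rc: tuple[int, int] | None, prev: np.ndarray | None) -> np.ndarray:
    """8-connected component containing the seed (or overlapping ``prev``)."""
    comp_labels, n = ndimage.label(labels2d, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(labels2d, dtype=bool)
    if seed_rc is not None:
        lab = comp_labels[seed_rc]
        return comp_labels == lab if lab > 0 else np.zeros_like(labels2d, dtype=bool)
    overlap = np.bincount(comp_labels[prev], minlength=n + 1)
    overlap[0] = 0
    lab = int(np.argmax(overlap))
    return comp_labels == lab if lab > 0 and overlap[lab] > 0 else np.zeros_like(labels2d, dtype=bool)


def segment_tumor(case: DceCase, seed: tuple[int, int, int], config: PipelineConfig | None = None) -> TumorMask:
    """Seed-grown tumor mask via per-slice spatial FCM + MRF propagation."""
    cfg = config or PipelineConfig()
    if case.breast_mask is None:
        raise ValueError("case needs a breast mask before tumor segmentation")
    seed = tuple(int(c) for c in seed)
    side_name = _seed_side(case.breast_mask, seed)
    side = case.breast_mask.left if side_name == "left" else case.breast_mask.right

    if cfg.tumor_input == "subtraction":
        inp = case.s1.data - case.s0.data
    elif cfg.tumor_input == "s1":
        inp = case.s1.data
    else:
        raise ValueError(f"unknown tumor_input {cfg.tumor_input!r}")

    x0, y0, z0 = seed
    params = MrfParams(beta=cfg.mrf_beta, max_iterations=cfg.mrf_max_iter, neighborhood=cfg.mrf_neighborhood)
    min_var = max(1e-6, 1e-6 * float(np.var(inp)))

    def refine_slice(z: int, init2d: np.ndarray, stats) -> np.ndarray:
        sl = inp[:, :, z] * side[:, :, z]
        out = mrf_refine(init2d[:, :, None], sl[:, :, None], params, class_stats=stats)
        return out[:, :, 0].astype(bool) & side[:, :, z]

    # seed slice: spatial FCM on the masked enhancement values
    sl_mask = side[:, :, z0]
    if not sl_mask[x0, y0]:
        raise SeedOutsideBreastError(f"seed {seed} outside the breast on its slice")
    vals = inp[:, :, z0][sl_mask]
    coords = np.nonzero(sl_mask)
    # seed-informed initialization: one centroid at the local enhancement
    # around the seed, the rest spread down to the background median
    patch = inp[max(x0 - 1, 0) : x0 + 2, max(y0 - 1, 0) : y0 + 2, z0]
    seed_level = float(patch.mean())
    bg_level = float(np.median(vals))
    init = np.linspace(bg_level, seed_level, cfg.fcm_classes)
    fcm = spatial_fcm(
        vals, coords=coords, shape=sl_mask.shape, c=cfg.fcm_classes, m=cfg.fcm_fuzzifier,
        alpha=cfg.fcm_alpha, tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter,
        init_centroids=init,
    )
    gap = float(fcm.centroids[-1] - fcm.centroids[0])
    s0_breast_mean = float(case.s0.data[side].mean())
    if gap < cfg.min_centroid_gap_frac * abs(s0_breast_mean):
        raise NoEnhancingLesionError(
            f"FCM centroid gap {gap:.1f} below {cfg.min_centroid_gap_frac} x breast mean "
            f"({s0_breast_mean:.1f}); no enhancing lesion at the seed"
        )
    hard = np.argmax(fcm.memberships, axis=1) == (cfg.fcm_classes - 1)  # top class = enhancing
    init2d = np.zeros(sl_mask.shape, dtype=np.int8)
    init2d[coords] = hard.astype(np.int8)
    seed_sl = inp[:, :, z0] * sl_mask
    refined = refine_slice(z0, init2d, _pooled_stats(seed_sl, init2d, min_var))
    comp = _slice_component(refined, (x0, y0), None)
    if not comp.any():
        raise NoEnhancingLesionError("empty tumor component at the seed slice")

    nz = inp.shape[2]
    mask = np.zeros(inp.shape, dtype=bool)
    mask[:, :, z0] = comp

    # propagate: warm-start each slice from the previous slice's component,
    # carrying the class statistics estimated on that slice (the adaptive
    # parameters), and search only within a dilation of the component so the
    # in-plane footprint evolves slice to slice instead of re-flooding
    for direction in (1, -1):
        prev = comp
        prev_z = z0
        z = z0 + direction
        while 0 <= z < nz and prev.any():
            prev_sl = inp[:, :, prev_z] * side[:, :, prev_z]
            stats = _pooled_stats(prev_sl, prev.astype(np.int8), min_var)
            if stats is None:
                break
            roi = ndimage.binary_dilation(prev, iterations=2) & side[:, :, z]
            init = (prev & roi).astype(np.int8)
            if not init.any():
                break
            refined = refine_slice(z, init, stats) & roi
            cur = _slice_component(refined, None, prev)
            if not cur.any():
                break
            mask[:, :, z] = cur
            prev = cur
            prev_z = z
            z += direction

    # final 26-connected component containing the seed
    labels3d, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    lab = labels3d[seed]
    if lab == 0:
        raise NoEnhancingLesionError("seed voxel lost during refinement")
    return TumorMask(mask=labels3d == lab, seed=seed)
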