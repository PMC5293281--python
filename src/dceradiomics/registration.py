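"""Inter-series registration by the 4-step window-correlation scheme.

The postcontrast series S-1 and S-2 are aligned to the precontrast S-0 by a
purely translational ("linearly shifting") model, estimated per slice and
aggregated by the median:

1. Sobel gradient filtering of each S-0 slice;
2. search for the maximum-information window (largest summed gradient
   magnitude) on the slice;
3. correlation matching of that window against the moving slice over all
   integer in-plane displacements within a search radius;
4. integer translation of the moving series by the aggregated shift.

Integer shifts only: subtraction maps stay free of resampling blur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import DceCase, PipelineConfig, Volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftEstimate:
    """Integer in-plane translation (voxels) with its correlation score."""

    dx: int
    dy: int
    score: float


def sobel_gradient(slice2d: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the standard 3x3 Sobel pair, edge-replicated."""
    a = np.asarray(slice2d, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < 3:
        raise ValueError(f"slice must be at least 3x3, got shape {a.shape}")
    gx = ndimage.sobel(a, axis=0, mode="nearest")
    gy = ndimage.sobel(a, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def find_max_information_window(gradient_slice: np.ndarray, window: int, valid: tuple | None = None) -> tuple[int, int]:
    """Corner (row, col) of the ``window x window`` patch with the largest
    summed gradient magnitude; ties break to the lexicographically smallest
    corner. ``valid`` optionally restricts corners to a (rows, cols) slice pair.
    """
    g = np.asarray(gradient_slice, dtype=np.float64)
    if window > min(g.shape):
        raise ValueError(f"window {window} exceeds slice extent {g.shape}")
    # integral image for exact window sums
    ii = np.zeros((g.shape[0] + 1, g.shape[1] + 1))
    ii[1:, 1:] = g.cumsum(0).cumsum(1)
    w = window
    sums = ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]
    if valid is not None:
        masked = np.full_like(sums, -np.inf)
        masked[valid] = sums[valid]
        sums = masked
    corner = np.unravel_index(int(np.argmax(sums)), sums.shape)  # first in C order == lexicographic min
    return int(corner[0]), int(corner[1])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:  # zero-variance window: score defined as 0
        return 0.0
    return float((a * b).sum() / denom)


def match_window(
    reference_slice: np.ndarray,
    moving_slice: np.ndarray,
    window_corner: tuple[int, int],
    window: int,
    radius: int,
) -> ShiftEstimate:
    """Exhaustive integer-displacement correlation match of one window.

    Scores every (dx, dy) with ``|dx|, |dy| <= radius`` by the Pearson
    correlation between the reference window and the moving window displaced
    by (dx, dy); returns the argmax. Ties break to the smallest Euclidean
    shift, then lexicographically.
    """
    ref = np.asarray(reference_slice, dtype=np.float64)
    mov = np.asarray(moving_slice, dtype=np.float64)
    i0, j0 = window_corner
    w = window
    if i0 - radius < 0 or j0 - radius < 0 or i0 + w + radius > mov.shape[0] or j0 + w + radius > mov.shape[1]:
        raise ValueError("window plus search radius does not fit inside the slice")
    ref_win = ref[i0 : i0 + w, j0 : j0 + w]
    best: tuple[float, int, int, int] | None = None  # (-score, d2, dx, dy)
    best_est = None
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            mov_win = mov[i0 + dx : i0 + dx + w, j0 + dy : j0 + dy + w]
            score = _pearson(ref_win, mov_win)
            key = (-score, dx * dx + dy * dy, dx, dy)
            if best is None or key < best:
                best = key
                best_est = ShiftEstimate(dx=dx, dy=dy, score=score)
    return best_est


def estimate_series_shift(reference: np.ndarray, moving: np.ndarray, window: int, radius: int) -> ShiftEstimate:
    """Median per-slice shift of ``moving`` relative to ``reference``."""
    nz = reference.shape[2]
    per_slice: list[ShiftEstimate] = []
    for z in range(nz):
        ref_sl = reference[:, :, z]
        if min(ref_sl.shape) < window + 2 * radius:
            continue
        grad = sobel_gradient(ref_sl)
        n0, n1 = grad.shape
        valid = (slice(radius, n0 - window - radius + 1), slice(radius, n1 - window - radius + 1))
        corner = find_max_information_window(grad, window, valid=valid)
        per_slice.append(match_window(ref_sl, moving[:, :, z], corner, window, radius))
    if not per_slice:
        raise ValueError("no slice large enough for the window + search radius")
    dx = int(round(float(np.median([e.dx for e in per_slice]))))
    dy = int(round(float(np.median([e.dy for e in per_slice]))))
    score = float(np.median([e.score for e in per_slice]))
    if max(abs(dx), abs(dy)) >= radius:
        log.warning("median shift (%d, %d) at the search boundary (radius %d)", dx, dy, radius)
    return ShiftEstimate(dx=dx, dy=dy, score=score)


def register_series(case: DceCase, config: PipelineConfig | None = None) -> tuple[DceCase, dict[str, ShiftEstimate]]:
    """Align S-1 and S-2 to S-0 by one integer in-plane translation each.

    Returns a new case with resampled (edge-padded) series plus the estimated
    shift per series. The estimate is the displacement of the moving series'
    content relative to S-0; the inverse is applied to align.
    """
    cfg = config or PipelineConfig()
    ref = case.s0.data
    estimates: dict[str, ShiftEstimate] = {}
    aligned = [case.s0]
    for name, vol in (("s1", case.s1), ("s2", case.s2)):
        est = estimate_series_shift(ref, vol.data, cfg.reg_window, cfg.reg_radius)
        estimates[name] = est
        moved = ndimage.shift(vol.data, (-est.dx, -est.dy, 0), order=0, mode="nearest")
        aligned.append(Volume(moved, vol.spacing, vol.origin))
    new_case = DceCase(
        case_id=case.case_id,
        series=tuple(aligned),
        age=case.age,
        menopausal=case.menopausal,
        subtype=case.subtype,
        breast_mask=case.breast_mask,
        tumor_mask=case.tumor_mask,
    )
    return new_case, estimates
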