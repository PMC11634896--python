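"""Post-processing of probability predictions.

Covers the four steps that turn raw out-of-fold predictions and probability
cubes into the final maps: precision-recall curves and the balanced
probability threshold (where precision equals recall as nearly as the curve
allows), 3-D Savitzky-Golay smoothing of the annual probability cubes
(local trivariate polynomial fits over a 5x5x5 time-space window),
the mean absolute difference layer (MADi) quantifying the smoothing impact,
and the integration of the two per-class cubes into an annual dominant-class
map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter
from sklearn.metrics import precision_recall_curve

from .core import (
    CLASS_CULTIVATED,
    CLASS_NATURAL,
    CLASS_OTHER,
    NODATA,
    DominantMap,
    ProbabilityCube,
)


@dataclass
class PRCurve:
    """Precision/recall at every distinct score threshold (ascending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    prevalence: float

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("curve arrays must share length")


@dataclass(frozen=True)
class ThresholdResult:
    """Balanced probability threshold and the scores achieved there."""

    class_name: str
    threshold: float
    precision: float
    recall: float
    f1: float


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """Precision-recall curve evaluated at every distinct predicted score.

    A sample is counted positive at threshold ``t`` when its score is
    ``>= t``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to build a PR curve")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # drop the final (precision=1, recall=0) sentinel that has no threshold
    return PRCurve(
        thresholds=thresholds,
        precision=precision[:-1],
        recall=recall[:-1],
        prevalence=float(labels.mean()),
    )


def balanced_threshold(curve: PRCurve, class_name: str = "") -> ThresholdResult:
    """The threshold where precision and recall are (nearly) equal.

    Minimizes ``|precision - recall|`` over the curve; ties break toward the
    lower threshold, which favours recall. Because any cutoff between two
    consecutive distinct scores yields the same confusion counts, the
    returned threshold is the midpoint of that equivalence interval (the
    minimizing score and the next-lower distinct score), again favouring
    recall when the trained cutoff is later applied to new probabilities.
    The F1 score at the chosen threshold is reported alongside.
    """
    gap = np.abs(curve.precision - curve.recall)
    i = int(np.argmin(gap))  # thresholds ascend, argmin takes the first
    p, r = float(curve.precision[i]), float(curve.recall[i])
    f1 = 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)
    if i > 0:
        threshold = float(curve.thresholds[i] + curve.thresholds[i - 1]) / 2.0
    else:
        threshold = float(curve.thresholds[i])
    return ThresholdResult(
        class_name=class_name,
        threshold=threshold,
        precision=p, recall=r, f1=f1,
    )


def _axis_window(n: int, window: int) -> tuple[int, int]:
    """Largest odd window not exceeding the axis length, and its poly order."""
    w = min(window, n)
    if w % 2 == 0:
        w -= 1
    w = max(w, 1)
    return w, min(3, w - 1)


def _masked_fit_value(
    block: np.ndarray,
    eval_off: tuple[int, int, int],
    orders: tuple[int, int, int],
) -> float:
    """Trivariate least-squares polynomial fit on the valid points of a
    window block, evaluated at the (possibly off-centre) target position."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in block.shape]
    tt, yy, xx = np.meshgrid(*axes, indexing="ij")
    valid = np.isfinite(block)
    n_valid = int(valid.sum())
    basis_terms = [
        (i, j, k)
        for i, j, k in product(range(orders[0] + 1), range(orders[1] + 1),
                               range(orders[2] + 1))
    ]
    if n_valid < len(basis_terms):
        return np.nan
    A = np.stack([
        (tt[valid] ** i) * (yy[valid] ** j) * (xx[valid] ** k)
        for i, j, k in basis_terms
    ], axis=1)
    beta, *_ = np.linalg.lstsq(A, block[valid], rcond=None)
    et, ey, ex = eval_off
    m = np.array([(et ** i) * (ey ** j) * (ex ** k) for i, j, k in basis_terms])
    return float(m @ beta)


def smooth_savgol3d(
    cube: ProbabilityCube,
    window: int = 5,
    polyorder: int = 3,
) -> ProbabilityCube:
    """3-D Savitzky-Golay smoothing of an annual probability cube.

    A trivariate polynomial (per-axis degree ``polyorder``) is fitted by
    least squares over a ``window``^3 neighbourhood in (time, row, col) and
    evaluated at the centre pixel. Near edges the window shifts to stay
    inside the cube and the fit is evaluated at the true pixel position.
    On gap-free data this tensor-product fit is computed separably with
    1-D Savitzky-Golay passes; windows touching no-data pixels fall back to
    an explicit masked fit that excludes them. Results are clipped to
    [0, 100] and re-quantized; no-data pixels stay 255.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    data = cube.data
    n_t = data.shape[0]
    if n_t < window:
        warnings.warn(
            f"cube has {n_t} years < window {window}; using a reduced "
            "temporal window", stacklevel=2,
        )

    vals = data.astype(np.float64)
    nanmask = data == NODATA
    vals[nanmask] = np.nan

    wins = [_axis_window(s, window) for s in data.shape]
    smoothed = np.nan_to_num(vals, nan=0.0)
    for axis, (w, order) in enumerate(wins):
        if w > 1:
            # mode="interp" fits the edge windows shifted inside the array
            # and evaluates the polynomial at the edge position
            smoothed = savgol_filter(
                smoothed, window_length=w, polyorder=min(polyorder, order),
                axis=axis, mode="interp",
            )

    # pixels whose (possibly edge-shifted) window can touch a no-data pixel
    # are recomputed with an explicit masked trivariate fit
    if nanmask.any():
        from scipy.ndimage import binary_dilation

        reach = tuple(2 * w - 1 for w, _o in wins)
        affected = binary_dilation(nanmask, structure=np.ones(reach, dtype=bool))
        bad = affected & ~nanmask
        orders = tuple(min(polyorder, o) for _w, o in wins)
        sizes = tuple(w for w, _o in wins)
        for t, y, x in zip(*np.nonzero(bad)):
            idx = (t, y, x)
            lo = [int(np.clip(idx[a] - sizes[a] // 2, 0,
                              data.shape[a] - sizes[a])) for a in range(3)]
            block = vals[lo[0]:lo[0] + sizes[0],
                         lo[1]:lo[1] + sizes[1],
                         lo[2]:lo[2] + sizes[2]]
            eval_off = tuple(
                idx[a] - lo[a] - (sizes[a] - 1) / 2.0 for a in range(3)
            )
            v = _masked_fit_value(block, eval_off, orders)
            if not np.isfinite(v):
                v = vals[t, y, x]  # too few valid neighbours: keep raw
            smoothed[t, y, x] = v

    out = np.full_like(data, NODATA)
    ok = np.isfinite(vals)
    out[ok] = np.clip(np.rint(smoothed[ok]), 0, 100).astype(np.uint8)
    return replace(cube, data=out, smoothed=True)


def compute_madi(raw: ProbabilityCube, smoothed: ProbabilityCube) -> np.ndarray:
    """Mean absolute difference between raw and smoothed probabilities.

    Per pixel, the absolute difference is averaged over the years in which
    both cubes are valid; pixels valid in no year are NaN.
    """
    if raw.data.shape != smoothed.data.shape:
        raise ValueError("cubes must share shape")
    a = raw.data.astype(np.float64)
    b = smoothed.data.astype(np.float64)
    valid = (raw.data != NODATA) & (smoothed.data != NODATA)
    diff = np.where(valid, np.abs(a - b), 0.0)
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        madi = diff.sum(axis=0) / n
    madi[n == 0] = np.nan
    return madi


def integrate_dominant(
    p_cultivated: ProbabilityCube,
    p_natural: ProbabilityCube,
    thresholds: tuple[ThresholdResult, ThresholdResult],
    priority_class: int = CLASS_NATURAL,
) -> DominantMap:
    """Threshold the two probability cubes into an annual dominant-class map.

    A pixel is coded 1 when only the cultivated probability reaches its
    threshold, 2 when only the natural probability does, ``priority_class``
    when both do (default: natural/semi-natural, the class with the higher
    cross-validated F1), and 0 when neither. No-data propagates from either
    cube.
    """
    if p_cultivated.data.shape != p_natural.data.shape:
        raise ValueError("probability cubes must share shape")
    thr_cult, thr_nat = thresholds
    pc = p_cultivated.data.astype(np.float64) / 100.0
    pn = p_natural.data.astype(np.float64) / 100.0
    cult = pc >= thr_cult.threshold
    nat = pn >= thr_nat.threshold
    out = np.full(p_cultivated.data.shape, CLASS_OTHER, dtype=np.uint8)
    out[cult] = CLASS_CULTIVATED
    out[nat] = CLASS_NATURAL
    out[cult & nat] = priority_class
    nodata = (p_cultivated.data == NODATA) | (p_natural.data == NODATA)
    out[nodata] = NODATA
    return DominantMap(
        years=list(p_cultivated.years), data=out,
        transform=p_cultivated.transform,
    )
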