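"""Detection thresholding and multiple-loess cross-array normalization.

Arrays are normalized on the log2 scale against a common reference (the
per-probe mean over arrays).  For each array the difference M = array - ref
is regressed on the average A = (array + ref)/2 with a degree-1 loess
(lowess) smoother and the fitted curve is subtracted; the pass over all
arrays is repeated until the largest per-value change drops below ``tol``.
A constant shift, or any smooth intensity-dependent distortion within the
smoother's reach, is thereby removed while ranks within an array are
preserved for monotone distortions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DetectionThreshold",
    "estimate_detection_threshold",
    "filter_detected",
    "to_log2",
    "multiloess_normalize",
    "NormalizationReport",
]


@dataclass(frozen=True)
class DetectionThreshold:
    """A log2 expression cutoff and the method that produced it."""
    value: float
    method: str

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("threshold must be finite")


def _check_matrix(matrix: pd.DataFrame):
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("probe and sample ids must be unique")
    if not np.all(np.isfinite(matrix.to_numpy())):
        raise ValueError("expression values must be finite")


def estimate_detection_threshold(matrix: pd.DataFrame, method: str = "valley",
                                 manual_value: float | None = None,
                                 quantile: float = 0.15) -> DetectionThreshold:
    """Choose the detected/undetected cutoff on pooled log2 values.

    ``valley`` places the cutoff at the density minimum between the two
    largest modes of a Gaussian kernel-density estimate of the pooled
    values — the automated counterpart of reading the cutoff off a
    distribution plot.  ``quantile`` returns the stated pooled quantile and
    ``manual`` returns ``manual_value`` unchanged.
    """
    _check_matrix(matrix)
    pooled = matrix.to_numpy().ravel()
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual method requires manual_value")
        return DetectionThreshold(float(manual_value), "manual")
    if method == "quantile":
        return DetectionThreshold(float(np.quantile(pooled, quantile)), "quantile")
    if method != "valley":
        raise ValueError(f"unknown threshold method {method!r}")

    if pooled.size > 200_000:
        # KDE cost is O(n_values * grid); deterministic thinning keeps the
        # pooled shape while bounding runtime on full-size studies
        pooled = np.sort(pooled)[:: pooled.size // 200_000 + 1]
    kde = gaussian_kde(pooled)
    grid = np.linspace(pooled.min(), pooled.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    # a mode must carry real mass; KDE tail wiggles are not modes
    peaks = peaks[dens[peaks] >= 0.05 * dens.max()]
    unimodal = ValueError(
        "pooled expression distribution looks unimodal; the valley method "
        "cannot locate a detection cutoff — use method='quantile' or "
        "method='manual'"
    )
    if len(peaks) < 2:
        raise unimodal
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    if dens[valley] > 0.95 * min(dens[lo], dens[hi]):
        raise unimodal   # no real dip between the candidate modes
    return DetectionThreshold(float(grid[valley]), "valley")


def filter_detected(matrix: pd.DataFrame, threshold: DetectionThreshold) -> pd.DataFrame:
    """Keep exactly the probes exceeding the cutoff in at least one sample,
    preserving probe order."""
    _check_matrix(matrix)
    keep = matrix.max(axis=1) > threshold.value
    if not keep.any():
        warnings.warn("no probe exceeds the detection threshold", stacklevel=2)
    return matrix.loc[keep]


def to_log2(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Log2-transform a linear-scale matrix after flooring at a small
    positive constant (avoids -inf for zero intensities)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log2(matrix.clip(lower=floor))


@dataclass
class NormalizationReport:
    """Convergence diagnostics of a multi-loess run."""
    iterations: int
    converged: bool
    max_change: float            # largest per-value change in the last pass
    residual_curvature: dict     # per array, max |lowess fit of M on A| at exit
    span: float
    tol: float

    def max_residual(self) -> float:
        return max(self.residual_curvature.values())


def _lowess_fit(m: np.ndarray, a: np.ndarray, span: float,
                delta_frac: float = 0.01) -> np.ndarray:
    delta = delta_frac * (a.max() - a.min())
    return lowess(m, a, frac=span, it=0, delta=delta, return_sorted=False)


def multiloess_normalize(matrix: pd.DataFrame, span: float = 0.4,
                         max_iter: int = 10, tol: float = 1e-3):
    """Iterative loess normalization of every array against the mean array.

    Returns ``(normalized, report)``.  Non-convergence within ``max_iter``
    passes issues a warning, not an error.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 arrays to normalize")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")

    values = matrix.to_numpy(dtype=float).copy()
    n_iter, max_change, converged = 0, np.inf, False
    for n_iter in range(1, max_iter + 1):
        reference = values.mean(axis=1)
        max_change = 0.0
        for j in range(values.shape[1]):
            m = values[:, j] - reference
            a = 0.5 * (values[:, j] + reference)
            fit = _lowess_fit(m, a, span)
            values[:, j] -= fit
            max_change = max(max_change, float(np.max(np.abs(fit))))
        if max_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"multi-loess did not converge in {max_iter} iterations "
            f"(last max change {max_change:.4g} > tol {tol:g})", stacklevel=2)

    reference = values.mean(axis=1)
    residual = {}
    for j, name in enumerate(matrix.columns):
        m = values[:, j] - reference
        a = 0.5 * (values[:, j] + reference)
        residual[name] = float(np.max(np.abs(_lowess_fit(m, a, span))))
    report = NormalizationReport(iterations=n_iter, converged=converged,
                                 max_change=max_change,
                                 residual_curvature=residual,
                                 span=span, tol=tol)
    normalized = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return normalized, report
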