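"""Leave-one-timepoint-out correlation resampling and edge retention.

For a T-timepoint series, each of the T jackknife iterations drops one
timepoint, recomputes the full R x R correlation matrix on the remaining
T-1 samples (so the p-value uses n = T-1), and applies the same Bonferroni
criterion as the static analysis. An edge's retention fraction is the share
of iterations in which it was significant; thresholding that fraction keeps
only connections whose significance does not hinge on a handful of
timepoints.

Each iteration recomputes the correlation from scratch; there is no
incremental downdating shortcut, so the result is definitionally identical
to the naive reference procedure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .fc import BinaryNetwork, METHODS, _corr_and_p, n_edge_universe
from .timeseries import RoiTimeSeries

DEFAULT_THETA = 0.85
DEFAULT_SWEEP_THETAS = (0.70, 0.80, 0.85, 0.90)


@dataclass
class JackknifeResult:
    """Per-edge retention fractions over T leave-one-out iterations."""

    method: str
    retention: np.ndarray  # R x R symmetric, diagonal nan
    n_iterations: int  # = T of the input series
    alpha: float
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.retention.shape[0]

    def counts(self) -> np.ndarray:
        """Integer significant-iteration counts (retention * T)."""
        return np.rint(np.nan_to_num(self.retention) * self.n_iterations).astype(int)


def _iteration_significance(data, t, method, m, alpha):
    sub = np.delete(data, t, axis=0)
    _r, p = _corr_and_p(sub, method)
    with np.errstate(invalid="ignore"):
        return p * m < alpha  # nan (diagonal) and degenerate p=1 both fail


def jackknife_fc(
    ts: RoiTimeSeries,
    method: str = "pearson",
    alpha: float = 0.05,
    n_jobs: int = 1,
) -> JackknifeResult:
    """Leave-one-timepoint-out significance retention for every ROI pair.

    Per iteration the full edge universe m = R*(R-1)/2 is Bonferroni-
    corrected at the same ``alpha`` as the static analysis, with n = T-1
    degrees-of-freedom input to the p-value. ``n_jobs`` distributes
    iterations with joblib; results are identical to the serial run because
    each iteration is independent and the counts are summed.
    """
    if method not in METHODS:
        raise ValueError(f"unknown correlation method {method!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    T, R = ts.data.shape
    if T < 5:
        raise ValueError("jackknife needs at least 5 timepoints")
    m = n_edge_universe(R)
    if n_jobs == 1:
        sigs = (
            _iteration_significance(ts.data, t, method, m, alpha) for t in range(T)
        )
        counts = sum(s.astype(np.int64) for s in sigs)
    else:
        sig_list = Parallel(n_jobs=n_jobs)(
            delayed(_iteration_significance)(ts.data, t, method, m, alpha)
            for t in range(T)
        )
        counts = sum(s.astype(np.int64) for s in sig_list)
    retention = counts / float(T)
    np.fill_diagonal(retention, np.nan)
    return JackknifeResult(
        method=method,
        retention=retention,
        n_iterations=T,
        alpha=alpha,
        roi_labels=list(ts.roi_labels),
    )


def retention_cutoff(theta: float, n_iterations: int) -> int:
    """Smallest significant-iteration count satisfying retention >= theta.

    Computed as ceil(theta * T) on the integer count scale to avoid
    float-equality traps (e.g. theta=0.85, T=294 -> 250).
    """
    return math.ceil(theta * n_iterations)


def retain_edges(jr: JackknifeResult, theta: float = DEFAULT_THETA) -> BinaryNetwork:
    """Edges significant in at least a fraction ``theta`` of iterations
    (inclusive, so theta=1 demands every iteration)."""
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    cutoff = retention_cutoff(theta, jr.n_iterations)
    counts = jr.counts()
    iu = np.triu_indices(jr.n_rois, k=1)
    keep = counts[iu] >= cutoff
    edges = frozenset((int(i), int(j)) for i, j, k in zip(iu[0], iu[1], keep) if k)
    prov = (
        f"jackknife {jr.method}; alpha={jr.alpha}; "
        f"bonferroni m={n_edge_universe(jr.n_rois)}; T={jr.n_iterations}; "
        f"theta={theta} (cutoff {cutoff} iterations)"
    )
    return BinaryNetwork(roi_labels=tuple(jr.roi_labels), edges=edges, provenance=prov)


@dataclass
class SweepResult:
    """Retained-edge counts across retention thresholds, over a cohort."""

    table: pd.DataFrame  # columns: theta, mean_edges, sd_edges, mean_density
    density_change_percent: float  # drop from the loosest to strictest theta

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def threshold_sweep(
    cohort_results: list[JackknifeResult],
    thetas=DEFAULT_SWEEP_THETAS,
) -> SweepResult:
    """Mean +/- SD of per-subject retained-edge counts at each threshold.

    SD is the sample standard deviation (ddof=1), 0 for a single subject.
    ``density_change_percent`` is the relative drop in mean edge count from
    the smallest to the largest theta.
    """
    if not cohort_results:
        raise ValueError("empty cohort")
    thetas = list(thetas)
    if thetas != sorted(thetas):
        raise ValueError("thetas must be sorted ascending")
    m = n_edge_universe(cohort_results[0].n_rois)
    rows = []
    for theta in thetas:
        counts = np.array(
            [len(retain_edges(jr, theta).edges) for jr in cohort_results], dtype=float
        )
        sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
        rows.append(
            {
                "theta": theta,
                "mean_edges": float(counts.mean()),
                "sd_edges": sd,
                "mean_density": float(counts.mean()) / m,
            }
        )
    table = pd.DataFrame(rows)
    first, last = table["mean_edges"].iloc[0], table["mean_edges"].iloc[-1]
    change = 100.0 * (first - last) / first if first > 0 else 0.0
    return SweepResult(table=table, density_change_percent=change)
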