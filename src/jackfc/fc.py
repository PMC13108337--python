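"""Static functional connectivity: correlation matrices, Fisher z, Bonferroni edges.

Pearson r is the product-moment coefficient; Spearman rho is Pearson applied
to average-rank-transformed columns. Two-tailed p-values come from
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom, the standard test of
zero correlation, which assumes temporally independent samples. Family-wise
error over the R*(R-1)/2 unique ROI pairs is controlled by Bonferroni.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman")


class PairEvalCounter:
    """Counts pairwise correlation evaluations performed while active.

    Use as a context manager::

        with PairEvalCounter() as counter:
            jackknife_fc(ts)
        counter.count  # pairs evaluated

    Every correlation-matrix computation on R ROIs adds R*(R-1)/2.
    """

    _active: list["PairEvalCounter"] = []

    def __init__(self) -> None:
        self.count = 0

    def __enter__(self) -> "PairEvalCounter":
        PairEvalCounter._active.append(self)
        return self

    def __exit__(self, *exc) -> None:
        PairEvalCounter._active.remove(self)


def _tally_pairs(n_pairs: int) -> None:
    for counter in PairEvalCounter._active:
        counter.count += n_pairs


def n_edge_universe(n_rois: int) -> int:
    """Number of unique unordered ROI pairs (the Bonferroni family size)."""
    return n_rois * (n_rois - 1) // 2


def fisher_z(r):
    """Fisher z transformation, atanh(r); |r| = 1 maps to signed infinity."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) > 1):
        raise ValueError("fisher_z requires |r| <= 1")
    with np.errstate(divide="ignore"):
        out = np.arctanh(arr)
    return out if isinstance(r, np.ndarray) else float(out)


def _corr_and_p(X: np.ndarray, method: str, roi_labels=None):
    """Correlation and two-tailed p matrices for the columns of X.

    Returns (r, p) with nan diagonals on p. Constant (zero-variance) columns
    yield undefined r (nan) and p = 1 off-diagonal, with a logged warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown correlation method {method!r}")
    X = np.asarray(X, dtype=float)
    n, R = X.shape
    if method == "spearman":
        X = rankdata(X, axis=0)  # average ranks for ties
    constant = np.ptp(X, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(np.asarray(r, dtype=float))
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    if constant.any():
        which = np.flatnonzero(constant)
        names = (
            [roi_labels[i] for i in which] if roi_labels is not None else list(which)
        )
        logger.warning(
            "constant signal in ROI(s) %s: correlations undefined, p set to 1", names
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) == 1.0] = 0.0  # t diverges: p = 0 by convention
    bad = constant[:, None] | constant[None, :]
    p[bad] = 1.0
    np.fill_diagonal(p, np.nan)
    _tally_pairs(n_edge_universe(R))
    return r, p


@dataclass
class CorrelationResult:
    """Correlation, Fisher-z and p-value matrices for one series and method."""

    method: str
    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_samples: int
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


def correlation_matrix(ts: RoiTimeSeries, method: str = "pearson") -> CorrelationResult:
    """All pairwise ROI correlations of one time series with edge-wise p-values.

    Spearman is computed as Pearson on average-rank-transformed columns;
    p-values use the t-statistic on n-2 df, two-tailed.
    """
    if ts.n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    r, p = _corr_and_p(ts.data, method, ts.roi_labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(r)
    return CorrelationResult(
        method=method,
        r=r,
        z=z,
        p=p,
        n_samples=ts.n_timepoints,
        roi_labels=list(ts.roi_labels),
    )


@dataclass(frozen=True)
class BinaryNetwork:
    """A binarized undirected network: the edge set over labeled ROIs."""

    roi_labels: tuple
    edges: frozenset
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        edges = frozenset((int(i), int(j)) for i, j in self.edges)
        R = len(self.roi_labels)
        for i, j in edges:
            if not (0 <= i < j < R):
                raise ValueError(f"invalid edge ({i}, {j}) for {R} ROIs")
        object.__setattr__(self, "edges", edges)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_labels(self) -> list[tuple[str, str]]:
        return [
            (self.roi_labels[i], self.roi_labels[j]) for i, j in sorted(self.edges)
        ]

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 matrix; the BrainNet Viewer .edge payload."""
        A = np.zeros((self.n_rois, self.n_rois), dtype=int)
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=0)

    def covered_rois(self) -> list[str]:
        """Labels of ROIs participating in at least one edge."""
        deg = self.degrees()
        return [lab for lab, d in zip(self.roi_labels, deg) if d > 0]


def bonferroni_binarize(res: CorrelationResult, alpha: float = 0.05) -> BinaryNetwork:
    """Edges whose Bonferroni-adjusted p is strictly below alpha.

    The family size is the full edge universe m = R*(R-1)/2 (2278 for the
    68-region Desikan-Killiany atlas); an edge is kept iff p * m < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = n_edge_universe(res.n_rois)
    iu = np.triu_indices(res.n_rois, k=1)
    with np.errstate(invalid="ignore"):
        keep = res.p[iu] * m < alpha
    edges = frozenset(
        (int(i), int(j)) for i, j, k in zip(iu[0], iu[1], keep) if k
    )
    prov = (
        f"static {res.method}; alpha={alpha}; bonferroni m={m}; n={res.n_samples}"
    )
    return BinaryNetwork(roi_labels=tuple(res.roi_labels), edges=edges, provenance=prov)
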