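"""Group-level aggregation: cross-subject consensus and the retention t-test.

Two independent criteria are combined. (1) Prevalence: an edge must appear
in the subject-level network of at least a fraction ``subject_fraction`` of
the cohort. (2) A one-sample two-tailed t-test of the per-subject retention
fractions against a chance-level null value (by default the nominal
significance level alpha = 0.05 of a null edge). Edges meeting both are
"reliable".
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fc import BinaryNetwork
from .jackknife import JackknifeResult, retain_edges

logger = logging.getLogger(__name__)


def _check_labels(label_sets) -> tuple:
    first = tuple(label_sets[0])
    for k, labels in enumerate(label_sets[1:], start=1):
        labels = tuple(labels)
        if labels != first:
            diverge = next(
                (a, b) for a, b in zip(first + ("<missing>",) * len(labels),
                                       labels + ("<missing>",) * len(first))
                if a != b
            )
            raise ValueError(
                f"ROI labels of subject {k} diverge from subject 0: "
                f"{diverge[1]!r} where {diverge[0]!r} expected"
            )
    return first


def group_consensus(
    nets: list[BinaryNetwork], subject_fraction: float = 0.85
) -> BinaryNetwork:
    """Edges present in at least ceil(subject_fraction * n) subject networks."""
    if not nets:
        raise ValueError("empty list of networks")
    if not 0 < subject_fraction <= 1:
        raise ValueError("subject_fraction must be in (0, 1]")
    labels = _check_labels([n.roi_labels for n in nets])
    need = math.ceil(subject_fraction * len(nets))
    tally: dict[tuple[int, int], int] = {}
    for net in nets:
        for e in net.edges:
            tally[e] = tally.get(e, 0) + 1
    edges = frozenset(e for e, c in tally.items() if c >= need)
    prov = (
        f"consensus over {len(nets)} subjects; subject_fraction={subject_fraction} "
        f"(>= {need} subjects)"
    )
    return BinaryNetwork(roi_labels=labels, edges=edges, provenance=prov)


def retention_ttest(retentions, null_value: float = 0.05) -> tuple[float, float]:
    """One-sample two-tailed t-test of retention fractions against a null.

    Zero variance across subjects is degenerate: p = 0 if the common value
    differs from the null (infinitely strong evidence under the model),
    p = 1 if it equals the null; a warning is logged either way.
    """
    vals = np.asarray(retentions, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(vals)):
        raise ValueError("retention fractions must be finite")
    n = vals.size
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if np.ptp(vals) == 0.0:  # identical values; mean may carry float noise
        common = float(vals[0])
        logger.warning(
            "zero variance across subjects in retention t-test (all values %g)", common
        )
        if common == null_value:
            return 0.0, 1.0
        return math.copysign(math.inf, common - null_value), 0.0
    t = (mean - null_value) / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return float(t), p


@dataclass
class GroupResult:
    """Cohort-level summary: prevalence, retention t-test, consensus edges."""

    roi_labels: list[str]
    prevalence: np.ndarray  # R x R fraction of subjects detecting each edge
    t_stat: np.ndarray
    p_group: np.ndarray
    consensus: BinaryNetwork
    n_subjects: int
    theta: float
    subject_fraction: float
    null_value: float


def group_analysis(
    jack_results: list[JackknifeResult],
    theta: float = 0.85,
    subject_fraction: float = 0.85,
    null_value: float = 0.05,
) -> GroupResult:
    """Aggregate per-subject jackknife results into a GroupResult.

    Subject networks come from ``retain_edges`` at ``theta``; prevalence is
    their cross-subject mean; the t-test runs edge-wise on the retention
    fractions against ``null_value`` with the degenerate-variance
    conventions of ``retention_ttest``.
    """
    if len(jack_results) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    labels = _check_labels([jr.roi_labels for jr in jack_results])
    nets = [retain_edges(jr, theta) for jr in jack_results]
    adj = np.stack([net.adjacency() for net in nets]).astype(float)
    prevalence = adj.mean(axis=0)
    np.fill_diagonal(prevalence, np.nan)

    stack = np.stack([jr.retention for jr in jack_results])  # S x R x R
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null_value) / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    # identical per-subject values: decide on the common value, not the
    # float-noise-contaminated mean/SD
    degenerate = np.ptp(stack, axis=0) == 0.0
    mean = np.where(degenerate, stack[0], mean)
    if degenerate.any():
        off = ~np.eye(stack.shape[1], dtype=bool)
        n_deg = int(np.count_nonzero(degenerate & off)) // 2
        if n_deg:
            logger.warning(
                "zero cross-subject variance for %d edge(s) in group t-test", n_deg
            )
        t[degenerate] = np.where(
            mean[degenerate] == null_value,
            0.0,
            np.copysign(np.inf, mean[degenerate] - null_value),
        )
        p[degenerate] = np.where(mean[degenerate] == null_value, 1.0, 0.0)
    np.fill_diagonal(t, np.nan)
    np.fill_diagonal(p, np.nan)
    consensus = group_consensus(nets, subject_fraction)
    return GroupResult(
        roi_labels=list(labels),
        prevalence=prevalence,
        t_stat=t,
        p_group=p,
        consensus=consensus,
        n_subjects=n,
        theta=theta,
        subject_fraction=subject_fraction,
        null_value=null_value,
    )


def reliable_edges(
    group: GroupResult,
    subject_nets: list[BinaryNetwork] | None = None,
    alpha: float = 0.05,
) -> BinaryNetwork:
    """Edges meeting both the prevalence consensus and the group t-test.

    The consensus operand defaults to ``group.consensus``; passing
    ``subject_nets`` recomputes it from those networks instead.
    """
    consensus = (
        group_consensus(subject_nets, group.subject_fraction)
        if subject_nets is not None
        else group.consensus
    )
    iu = np.triu_indices(len(group.roi_labels), k=1)
    with np.errstate(invalid="ignore"):
        sig = group.p_group[iu] < alpha
    sig_edges = {(int(i), int(j)) for i, j, k in zip(iu[0], iu[1], sig) if k}
    edges = frozenset(consensus.edges & sig_edges)
    prov = (
        f"{consensus.provenance}; AND group t-test p < {alpha} "
        f"(null retention {group.null_value}, theta={group.theta})"
    )
    return BinaryNetwork(
        roi_labels=tuple(group.roi_labels), edges=edges, provenance=prov
    )
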