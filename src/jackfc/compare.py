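"""Paired comparison of two edge detectors on the same ROI pair universe.

Both methods classify every unordered ROI pair as detected or not, giving a
paired 2x2 table whose discordant cells feed McNemar's exact test: under the
null of equal detection rates the b discordant-one-way pairs among the
b + c discordant pairs are Binomial(b+c, 1/2), and the two-sided p-value is
twice the smaller tail (capped at 1). Edge differences are tagged by
hemisphere from the ROI label prefixes (``lh_``/``lh-`` left,
``rh_``/``rh-`` right).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fc import BinaryNetwork, n_edge_universe

HEMISPHERE_PREFIXES = {
    "lh_": "left",
    "lh-": "left",
    "rh_": "right",
    "rh-": "right",
}


@dataclass(frozen=True)
class PairedTable:
    """Counts over all R(R-1)/2 pairs: both, only-1, only-2, neither."""

    a: int  # detected by both
    b: int  # only by method 1
    c: int  # only by method 2
    d: int  # by neither

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def paired_table(net1: BinaryNetwork, net2: BinaryNetwork) -> PairedTable:
    """The 2x2 detection table of two networks on the same ROI universe."""
    if tuple(net1.roi_labels) != tuple(net2.roi_labels):
        raise ValueError("networks have different ROI labels")
    m = n_edge_universe(net1.n_rois)
    a = len(net1.edges & net2.edges)
    b = len(net1.edges - net2.edges)
    c = len(net2.edges - net1.edges)
    return PairedTable(a=a, b=b, c=c, d=m - a - b - c)


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant counts.

    p = min(1, 2 * sum_{k<=min(b,c)} C(b+c, k) / 2^(b+c)); b = c = 0 gives
    p = 1 by convention (no discordant information).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def mcnemar_chi2(b: int, c: int, correction: bool = True) -> float:
    """Chi-square McNemar approximation (continuity-corrected by default)."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if correction else (b - c) ** 2
    return float(stats.chi2.sf(num / n, df=1))


def classify_edge_hemisphere(edge: tuple[int, int], roi_labels) -> str:
    """'left', 'right', or 'inter' from the two ROI label prefixes."""
    sides = []
    for idx in edge:
        label = roi_labels[idx]
        for prefix, side in HEMISPHERE_PREFIXES.items():
            if label.startswith(prefix):
                sides.append(side)
                break
        else:
            raise ValueError(
                f"ROI label {label!r} has no recognized hemisphere prefix "
                f"({'/'.join(HEMISPHERE_PREFIXES)})"
            )
    return sides[0] if sides[0] == sides[1] else "inter"


def hemisphere_tally(edges, roi_labels) -> dict[str, int]:
    tally = {"left": 0, "right": 0, "inter": 0}
    for e in edges:
        tally[classify_edge_hemisphere(e, roi_labels)] += 1
    return tally


@dataclass
class ComparisonResult:
    """Full paired comparison: table, exact McNemar p, edge differences."""

    roi_labels: list[str]
    table: PairedTable
    p_mcnemar: float
    gained_edges: list[tuple[int, int]]  # detected by method 1 only
    lost_edges: list[tuple[int, int]]  # detected by method 2 only
    gained_tally: dict[str, int] = field(default_factory=dict)
    lost_tally: dict[str, int] = field(default_factory=dict)
    label1: str = "method1"
    label2: str = "method2"

    def summary(self) -> str:
        t = self.table
        lines = [
            f"paired comparison: {self.label1} vs {self.label2}",
            f"edge universe: {t.total} ROI pairs",
            f"both: {t.a}  only {self.label1}: {t.b}  "
            f"only {self.label2}: {t.c}  neither: {t.d}",
            f"exact McNemar p = {self.p_mcnemar:.3g}",
            f"{self.label1}-only hemisphere tally: {self.gained_tally}",
            f"{self.label2}-only hemisphere tally: {self.lost_tally}",
        ]
        return "\n".join(lines)


def diff_report(
    net1: BinaryNetwork,
    net2: BinaryNetwork,
    label1: str = "method1",
    label2: str = "method2",
) -> ComparisonResult:
    """Assemble the paired table, exact McNemar p, sorted edge differences
    and hemisphere tallies for two networks on the same ROI universe."""
    table = paired_table(net1, net2)
    gained = sorted(net1.edges - net2.edges)
    lost = sorted(net2.edges - net1.edges)
    return ComparisonResult(
        roi_labels=list(net1.roi_labels),
        table=table,
        p_mcnemar=mcnemar_exact(table.b, table.c),
        gained_edges=gained,
        lost_edges=lost,
        gained_tally=hemisphere_tally(gained, net1.roi_labels),
        lost_tally=hemisphere_tally(lost, net1.roi_labels),
        label1=label1,
        label2=label2,
    )


# ---------------------------------------------------------------------------
# BrainNet Viewer export
# ---------------------------------------------------------------------------

def write_brainnet(
    net: BinaryNetwork,
    node_path,
    edge_path,
    coords: np.ndarray | None = None,
) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for a network.

    ``.node`` rows are ``x y z color size label`` with node size set to the
    ROI degree; coordinates default to zeros when none are supplied (the
    viewer still loads them, positions are then meaningless). ``.edge`` is
    the R x R binary adjacency matrix, whitespace-separated.
    """
    R = net.n_rois
    if coords is None:
        coords = np.zeros((R, 3))
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (R, 3):
        raise ValueError(f"coords must have shape ({R}, 3)")
    deg = net.degrees()
    with open(node_path, "w") as f:
        for k in range(R):
            x, y, z = coords[k]
            f.write(f"{x:.6g}\t{y:.6g}\t{z:.6g}\t1\t{deg[k]}\t{net.roi_labels[k]}\n")
    np.savetxt(edge_path, net.adjacency(), fmt="%d", delimiter="\t")
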