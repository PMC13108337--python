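"""Tab-separated serialization of matrices, edge lists and networks.

One dialect throughout: labeled square matrices have ROI labels as both
header row and first column; edge lists are
``roi_label_a<TAB>roi_label_b<TAB><value columns...>`` with a header.
Floats are written with 17 significant digits so round trips are exact.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fc import BinaryNetwork, CorrelationResult, n_edge_universe
from .jackknife import JackknifeResult

FLOAT_FMT = "%.17g"


def write_matrix_tsv(matrix: np.ndarray, roi_labels, path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(roi_labels), columns=list(roi_labels))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="roi")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), list(df.columns)


def write_correlation_result(res: CorrelationResult, prefix: str | Path) -> list[Path]:
    """Write r/z/p matrices as ``<prefix>.{r,z,p}.tsv``; returns the paths."""
    prefix = Path(prefix)
    paths = []
    for name, mat in (("r", res.r), ("z", res.z), ("p", res.p)):
        path = prefix.with_suffix(f".{name}.tsv")
        write_matrix_tsv(mat, res.roi_labels, path)
        paths.append(path)
    return paths


def write_edge_list(
    net: BinaryNetwork,
    path,
    value_matrices: dict[str, np.ndarray] | None = None,
) -> None:
    """Edge list with optional per-edge value columns (e.g. r, p_adj)."""
    value_matrices = value_matrices or {}
    cols = list(value_matrices)
    with open(path, "w") as f:
        f.write("\t".join(["roi_a", "roi_b", *cols]) + "\n")
        for i, j in sorted(net.edges):
            vals = [FLOAT_FMT % value_matrices[c][i, j] for c in cols]
            f.write(
                "\t".join([net.roi_labels[i], net.roi_labels[j], *vals]) + "\n"
            )
        f.write(f"# provenance: {net.provenance}\n")


def read_edge_list(path, roi_labels) -> BinaryNetwork:
    """Read an edge list written by ``write_edge_list`` back to a network."""
    roi_labels = list(roi_labels)
    index = {lab: k for k, lab in enumerate(roi_labels)}
    edges = set()
    provenance = ""
    with open(path) as f:
        header = f.readline()
        if not header.startswith("roi_a"):
            raise ValueError(f"{path}: missing edge-list header")
        for line in f:
            if line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            try:
                i, j = index[parts[0]], index[parts[1]]
            except KeyError as exc:
                raise ValueError(f"{path}: unknown ROI label {exc}") from exc
            edges.add((min(i, j), max(i, j)))
    return BinaryNetwork(roi_labels=tuple(roi_labels), edges=frozenset(edges), provenance=provenance)


def write_static_network(
    res: CorrelationResult, net: BinaryNetwork, path
) -> None:
    """Edge list with r and Bonferroni-adjusted p columns."""
    m = n_edge_universe(res.n_rois)
    p_adj = np.minimum(res.p * m, 1.0)
    write_edge_list(net, path, {"r": res.r, "p_adj": p_adj})


def write_retention(jr: JackknifeResult, path) -> None:
    write_matrix_tsv(jr.retention, jr.roi_labels, path)


def read_retention(path, method: str, alpha: float, n_iterations: int) -> JackknifeResult:
    mat, labels = read_matrix_tsv(path)
    return JackknifeResult(
        method=method,
        retention=mat,
        n_iterations=n_iterations,
        alpha=alpha,
        roi_labels=labels,
    )
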