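"""ROI-averaged BOLD time series: the T x R container every stage consumes.

The tab-separated on-disk dialect is: a header row of ROI labels, then one
row of numbers per timepoint. Label order defines the canonical ROI indexing
for every downstream matrix and edge list.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

MIN_TIMEPOINTS = 4  # smallest T with a defined correlation p-value after one leave-out


def default_roi_labels() -> list[str]:
    """The 68 Desikan-Killiany cortical parcel names with lh_/rh_ prefixes."""
    text = resources.files("jackfc.data").joinpath("dk68_labels.txt").read_text()
    return text.split()


@dataclass
class RoiTimeSeries:
    """One subject's T x R matrix of ROI-averaged signal.

    Parameters
    ----------
    subject_id
        Free-form identifier; used in file names and the run manifest.
    data
        Array of shape (n_timepoints, n_rois), arbitrary signal units.
    roi_labels
        One label per column; order is the canonical ROI indexing.
    """

    subject_id: str
    data: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (timepoints x ROIs) array")
        if self.data.shape[0] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} timepoints, got {self.data.shape[0]}"
            )
        self.roi_labels = [str(x) for x in self.roi_labels]
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.data.shape[1]} data columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            seen: set[str] = set()
            dup = next(x for x in self.roi_labels if x in seen or seen.add(x))
            raise ValueError(f"duplicate ROI label: {dup!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data, columns=self.roi_labels)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str | None = None) -> "RoiTimeSeries":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # re-raise with file context
            raise ValueError(f"could not parse time-series file {path}: {exc}") from exc
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(
                f"{path}: column {non_numeric[0]!r} contains non-numeric values"
            )
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df[col].isna().idxmax()) + 2  # 1-based, after header
            raise ValueError(f"{path}: missing value at line {row}, column {col!r}")
        return cls(
            subject_id=subject_id or path.stem,
            data=df.to_numpy(dtype=float),
            roi_labels=list(df.columns),
        )


def read_roi_labels(path: str | Path) -> list[str]:
    """Read an ROI label list, one label per line, ignoring blanks."""
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in {path}")
    return labels
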