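"""Analysis configuration: every threshold in one validated, serializable place."""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .fc import METHODS
from .jackknife import DEFAULT_SWEEP_THETAS, DEFAULT_THETA


@dataclass
class AnalysisConfig:
    """Parameters of the full static + jackknife pipeline.

    Attributes
    ----------
    method
        Correlation for the static analysis ('pearson' or 'spearman'); the
        jackknife stages always run both for the paired comparisons.
    alpha
        Edge-wise significance level before Bonferroni correction.
    theta
        Jackknife retention threshold (fraction of iterations, inclusive).
    sweep_thetas
        Thresholds evaluated by the retention sweep.
    subject_fraction
        Cohort prevalence required for a consensus edge.
    null_value
        Chance-level retention for the group one-sample t-test.
    seed
        Master seed for any simulation steps.
    n_jobs
        joblib workers for jackknife iterations; results are identical to
        the serial run.
    """

    method: str = "pearson"
    alpha: float = 0.05
    theta: float = DEFAULT_THETA
    sweep_thetas: tuple = DEFAULT_SWEEP_THETAS
    subject_fraction: float = 0.85
    null_value: float = 0.05
    seed: int = 0
    n_jobs: int = 1
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("theta", "subject_fraction", "null_value"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        self.sweep_thetas = tuple(float(t) for t in self.sweep_thetas)
        if any(not 0 < t <= 1 for t in self.sweep_thetas):
            raise ValueError("sweep_thetas must be in (0, 1]")
        if list(self.sweep_thetas) != sorted(self.sweep_thetas):
            raise ValueError("sweep_thetas must be sorted ascending")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_thetas"] = list(self.sweep_thetas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a key-value mapping")
        return cls.from_dict(d)
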