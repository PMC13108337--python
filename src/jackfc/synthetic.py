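"""Synthetic BOLD cohorts with planted inter-ROI correlation structure.

The generator draws each subject's T x R series from a zero-mean multivariate
normal whose correlation matrix is the identity plus the user's planted
edges, scaled by ``noise_sd``. Time samples are independent by default (an
optional AR(1) coefficient introduces temporal autocorrelation to probe
robustness of the significance tests, which assume independence). Optional
single-timepoint outliers add a large shared excursion to chosen ROIs,
emulating a motion spike that corrupts specific edges.

Per-subject random substreams are spawned from the master seed via
``numpy.random.SeedSequence(master_seed, spawn_key=(subject_index,))``, so a
cohort is reproducible element-for-element and adding subjects never changes
earlier subjects' data.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .timeseries import RoiTimeSeries, default_roi_labels

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic cohort with known ground-truth connectivity.

    Parameters
    ----------
    n_rois, n_timepoints
        Matrix dimensions; defaults mirror a 68-parcel cortical atlas and a
        294-timepoint task run.
    roi_labels
        Hemisphere-prefixed labels (``lh_``/``rh_``); defaults to the 68
        Desikan-Killiany names. Must have length ``n_rois``.
    planted_edges
        ``(roi_i, roi_j, target_correlation)`` triples; all other ROI pairs
        are uncorrelated.
    noise_sd
        Marginal standard deviation of every ROI signal.
    outliers
        ``(timepoint, roi_indices, magnitude)`` triples; each adds
        ``magnitude * noise_sd`` to the listed ROIs at one timepoint.
    ar_coeff
        AR(1) coefficient of the innovations in time; 0 (the default) gives
        temporally independent samples, matching the significance model.
    """

    n_rois: int = 68
    n_timepoints: int = 294
    roi_labels: list[str] | None = None
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    outliers: list[tuple[int, list[int], float]] = field(default_factory=list)
    n_subjects: int = 1
    master_seed: int = 0
    ar_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_labels is None:
            if self.n_rois == 68:
                self.roi_labels = default_roi_labels()
            else:
                half = (self.n_rois + 1) // 2
                self.roi_labels = [
                    f"{'lh' if k < half else 'rh'}_roi{k:03d}" for k in range(self.n_rois)
                ]
        if len(self.roi_labels) != self.n_rois:
            raise ValueError(
                f"{len(self.roi_labels)} labels for n_rois={self.n_rois}"
            )
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in (-1, 1)")
        for i, j, rho in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) must join distinct ROIs")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"planted edge ({i}, {j}) outside 0..{self.n_rois - 1}")
            if not -1 < rho < 1:
                raise ValueError(f"target correlation {rho} outside (-1, 1)")
        for t, rois, _mag in self.outliers:
            if not 0 <= t < self.n_timepoints:
                raise ValueError(f"outlier timepoint {t} outside [0, {self.n_timepoints})")
            for k in rois:
                if not 0 <= k < self.n_rois:
                    raise ValueError(f"outlier ROI index {k} outside 0..{self.n_rois - 1}")

    # -- config round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "n_timepoints": self.n_timepoints,
            "roi_labels": list(self.roi_labels),
            "planted_edges": [[int(i), int(j), float(r)] for i, j, r in self.planted_edges],
            "noise_sd": self.noise_sd,
            "outliers": [[int(t), [int(k) for k in rois], float(m)] for t, rois, m in self.outliers],
            "n_subjects": self.n_subjects,
            "master_seed": self.master_seed,
            "ar_coeff": self.ar_coeff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["planted_edges"] = [tuple(e) for e in d.get("planted_edges", [])]
        d["outliers"] = [
            (int(t), list(rois), float(m)) for t, rois, m in d.get("outliers", [])
        ]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Nearest positive semi-definite matrix with unit diagonal (eigenvalue
    clipping followed by diagonal renormalization)."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    repaired = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_target_covariance(spec: SyntheticSpec, repair: bool = False) -> np.ndarray:
    """The R x R target correlation matrix implied by the planted edges.

    Unit diagonal; off-diagonal equals the target correlation for planted
    edges and 0 elsewhere. Raises if the result is not positive
    semi-definite unless ``repair=True``, which projects to the nearest PSD
    correlation matrix.
    """
    C = np.eye(spec.n_rois)
    for i, j, rho in spec.planted_edges:
        if C[i, j] != 0.0 and C[i, j] != rho:
            raise ValueError(f"conflicting target correlations for edge ({i}, {j})")
        C[i, j] = C[j, i] = rho
    eigvals = np.linalg.eigvalsh(C)
    if eigvals[0] < -1e-10:
        if not repair:
            raise ValueError(
                "planted edges imply a non-positive-semi-definite correlation "
                f"matrix (smallest eigenvalue {eigvals[0]:.6g}); pass repair=True "
                "to project to the nearest PSD correlation matrix"
            )
        C = nearest_psd(C)
    return C


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject substream; see module docstring."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    )


def simulate_subject(
    spec: SyntheticSpec, subject_index: int, repair: bool = False
) -> RoiTimeSeries:
    """Draw one subject's T x R series from the planted-correlation model."""
    if not 0 <= subject_index < max(spec.n_subjects, subject_index + 1):
        raise ValueError("subject_index must be non-negative")
    C = build_target_covariance(spec, repair=repair)
    rng = _subject_rng(spec.master_seed, subject_index)
    # factor via eigh so that rank-deficient (repaired) targets still sample
    w, v = np.linalg.eigh(C)
    L = v * np.sqrt(np.clip(w, 0.0, None))
    innov = rng.standard_normal((spec.n_timepoints, spec.n_rois))
    if spec.ar_coeff != 0.0:
        phi = spec.ar_coeff
        scale = math.sqrt(1.0 - phi * phi)
        for t in range(1, spec.n_timepoints):
            innov[t] = phi * innov[t - 1] + scale * innov[t]
    data = spec.noise_sd * (innov @ L.T)
    for t, rois, mag in spec.outliers:
        data[t, list(rois)] += mag * spec.noise_sd
    return RoiTimeSeries(
        subject_id=f"sub-{subject_index:04d}",
        data=data,
        roi_labels=list(spec.roi_labels),
    )


def make_cohort(spec: SyntheticSpec, repair: bool = False) -> list[RoiTimeSeries]:
    """``n_subjects`` independent subjects sharing the planted structure."""
    return [simulate_subject(spec, k, repair=repair) for k in range(spec.n_subjects)]


def disjoint_planted_edges(
    n_rois: int, n_edges: int, rho: float, rng: np.random.Generator | None = None
) -> list[tuple[int, int, float]]:
    """Planted edges on disjoint ROI pairs (guaranteed positive definite).

    Pairing disjoint ROIs keeps the target correlation matrix block diagonal
    in 2 x 2 blocks, so any |rho| < 1 is admissible regardless of edge count.
    """
    if 2 * n_edges > n_rois:
        raise ValueError(f"{n_edges} disjoint pairs need at least {2 * n_edges} ROIs")
    order = np.arange(n_rois) if rng is None else rng.permutation(n_rois)
    return [
        (int(min(order[2 * k], order[2 * k + 1])), int(max(order[2 * k], order[2 * k + 1])), rho)
        for k in range(n_edges)
    ]


# ---------------------------------------------------------------------------
# Masked-edge fixture: an edge the static test misses but leave-one-out keeps
# ---------------------------------------------------------------------------

def _masked_pair_columns(T: int, n_signal: int, eps: float):
    """Deterministic pair of columns: a strong shared signal carried by
    ``n_signal`` high-leverage timepoints, diluted by anti-correlated
    low-amplitude timepoints elsewhere.

    Removing any dilution timepoint strictly increases the pair correlation
    (its cross-product contributes -eps^2), while removing a signal
    timepoint decreases it. Near the significance boundary this makes the
    edge invisible to the full-sample test yet significant in the
    (T - n_signal) / T leave-one-out iterations that drop a dilution point.
    """
    n_dil = T - n_signal
    s = np.linspace(-1.0, 1.0, n_signal)
    a = np.tile([1.0, -1.0], (n_dil + 1) // 2)[:n_dil]
    x = np.empty(T)
    y = np.empty(T)
    sig_idx = np.linspace(0, T - 1, n_signal).round().astype(int)
    mask = np.zeros(T, bool)
    mask[sig_idx] = True
    x[mask] = s
    y[mask] = s
    x[~mask] = eps * a
    y[~mask] = -eps * a
    return x, y


def _pair_p_adj(x: np.ndarray, y: np.ndarray, m: int):
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return min(1.0, 2.0 * stats.t.sf(abs(t), n - 2) * m), r


def masked_edge_series(
    n_rois: int = 6,
    n_timepoints: int = 294,
    masked_pairs: list[tuple[int, int]] | None = None,
    strong_edges: list[tuple[int, int, float]] | None = None,
    alpha: float = 0.05,
    theta: float = 0.85,
    seed: int = 0,
    roi_labels: list[str] | None = None,
) -> RoiTimeSeries:
    """A subject in which each masked pair defeats the static test but not
    the jackknife retention criterion.

    The masked pair's columns are replaced by a calibrated deterministic
    pattern (see ``_masked_pair_columns``): the full-sample Bonferroni-
    adjusted p lands just above ``alpha``, while at least ``ceil(theta*T)``
    of the leave-one-out iterations are individually significant. The
    remaining ROIs follow the ordinary planted-correlation model, so
    ``strong_edges`` are comfortably significant under both methods.

    Raises RuntimeError if the calibration cannot realize the property for
    the requested geometry (e.g. theta too close to 1 for the given T).
    """
    T = n_timepoints
    masked_pairs = masked_pairs or [(2, 3)]
    strong_edges = strong_edges or [(0, 1, 0.8)]
    m = n_rois * (n_rois - 1) // 2
    # signal timepoints must be fewer than the non-retained share of iterations
    n_signal = min(int((1.0 - theta) * T) - 2, 40)
    if n_signal < 4:
        raise RuntimeError(
            f"cannot build a masked edge with T={T}, theta={theta}: too few "
            "leave-out iterations left for the signal timepoints"
        )
    used = {k for pair in masked_pairs for k in pair}
    for i, j, _ in strong_edges:
        if i in used or j in used:
            raise ValueError("strong edges must not touch masked-pair ROIs")
    spec = SyntheticSpec(
        n_rois=n_rois,
        n_timepoints=T,
        roi_labels=roi_labels,
        planted_edges=strong_edges,
        master_seed=seed,
        n_subjects=1,
    )
    ts = simulate_subject(spec, 0)
    data = ts.data.copy()

    # calibrate the dilution amplitude on the r > 0 branch: p_adj crosses
    # alpha from below as eps grows
    lo, hi = 1e-3, 50.0
    for _ in range(300):
        mid = 0.5 * (lo + hi)
        pa, r = _pair_p_adj(*_masked_pair_columns(T, n_signal, mid), m)
        if r > 0 and pa < alpha:
            lo = mid
        else:
            hi = mid
    cutoff = math.ceil(theta * T)
    for mult in (1.0001, 1.00001, 1.000001):
        eps = hi * mult
        x, y = _masked_pair_columns(T, n_signal, eps)
        pa_static, _ = _pair_p_adj(x, y, m)
        if pa_static <= alpha:
            continue
        n_sig = 0
        for t in range(T):
            pa_loo, _ = _pair_p_adj(np.delete(x, t), np.delete(y, t), m)
            if pa_loo < alpha:
                n_sig += 1
        if n_sig >= cutoff:
            break
    else:
        raise RuntimeError(
            "masked-edge calibration failed: no dilution amplitude gives a "
            "statically non-significant edge retained by the jackknife"
        )
    # successive masked pairs get time-rolled copies of the calibrated
    # pattern so they do not correlate with each other (odd shifts keep the
    # alternating dilution parts orthogonal); the leave-one-out property is
    # invariant under the roll
    for k, (i, j) in enumerate(masked_pairs):
        shift = 2 * k + 1 if k else 0
        data[:, i] = np.roll(x, shift)
        data[:, j] = np.roll(y, shift)
    if len(masked_pairs) > 1:
        cols = [c for pair in masked_pairs for c in pair]
        for a_i, ci in enumerate(cols):
            for cj in cols[a_i + 1:]:
                if {ci, cj} in [set(p) for p in masked_pairs]:
                    continue
                pa_cross, _ = _pair_p_adj(data[:, ci], data[:, cj], m)
                if pa_cross < alpha:
                    raise RuntimeError(
                        "masked-pair patterns leak correlation across pairs "
                        f"(ROIs {ci}, {cj}); use fewer masked pairs"
                    )
    return RoiTimeSeries(
        subject_id=ts.subject_id, data=data, roi_labels=list(ts.roi_labels)
    )
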