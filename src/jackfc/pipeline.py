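"""End-to-end pipeline: per-subject estimation, group consensus, comparisons.

Given a cohort of ROI time series the pipeline writes, per subject, the
static Bonferroni network and the jackknife retention matrix plus retained
network for both Pearson and Spearman; at cohort level the retention
threshold sweep, group consensus and reliable-edge networks per method, the
pairwise method comparisons (jackknife-Pearson vs static, jackknife-Spearman
vs static, jackknife-Pearson vs jackknife-Spearman), BrainNet Viewer
exports, and a machine-readable manifest capturing every parameter. The
manifest contains no timestamps, so a rerun with the same inputs and
configuration reproduces every output byte for byte.

Per-subject outputs already on disk are reused when ``resume=True``.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import io as jio
from .compare import classify_edge_hemisphere, diff_report, write_brainnet
from .config import AnalysisConfig
from .fc import bonferroni_binarize, correlation_matrix
from .group import group_analysis, group_consensus, reliable_edges
from .jackknife import jackknife_fc, retain_edges, threshold_sweep
from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

JACKKNIFE_METHODS = ("pearson", "spearman")


def _subject_paths(subj_dir: Path, subject_id: str) -> dict:
    base = subj_dir / subject_id
    paths = {"static": Path(f"{base}.static.edges.tsv")}
    for meth in JACKKNIFE_METHODS:
        paths[f"retention.{meth}"] = Path(f"{base}.retention.{meth}.tsv")
        paths[f"jc.{meth}"] = Path(f"{base}.jc.{meth}.edges.tsv")
    return paths


def _process_subject(ts: RoiTimeSeries, config: AnalysisConfig, subj_dir: Path,
                     resume: bool):
    """Static network + jackknife results for one subject (cached on disk)."""
    paths = _subject_paths(subj_dir, ts.subject_id)
    static_res = correlation_matrix(ts, config.method)
    static_net = bonferroni_binarize(static_res, config.alpha)
    jio.write_static_network(static_res, static_net, paths["static"])

    jack = {}
    for meth in JACKKNIFE_METHODS:
        rpath = paths[f"retention.{meth}"]
        if resume and rpath.exists():
            jack[meth] = jio.read_retention(
                rpath, meth, config.alpha, ts.n_timepoints
            )
            logger.info("%s: reusing %s", ts.subject_id, rpath.name)
        else:
            t0 = time.perf_counter()
            jack[meth] = jackknife_fc(
                ts, meth, config.alpha, n_jobs=config.n_jobs
            )
            logger.info(
                "%s: jackknife %s (%d iterations) in %.2fs",
                ts.subject_id, meth, ts.n_timepoints, time.perf_counter() - t0,
            )
            jio.write_retention(jack[meth], rpath)
        net = retain_edges(jack[meth], config.theta)
        jio.write_edge_list(net, paths[f"jc.{meth}"], {"retention": jack[meth].retention})
    return static_net, jack


def run_pipeline(
    config: AnalysisConfig,
    cohort: list[RoiTimeSeries] | None = None,
    series_paths: list[str | Path] | None = None,
    out_dir: str | Path = "jackfc_run",
    resume: bool = False,
) -> Path:
    """Run the full analysis and return the run directory.

    Exactly one of ``cohort`` (in-memory series) or ``series_paths``
    (tab-separated files) must be given.
    """
    if (cohort is None) == (series_paths is None):
        raise ValueError("pass exactly one of cohort or series_paths")
    if series_paths is not None:
        cohort = [RoiTimeSeries.from_tsv(p) for p in series_paths]
    if not cohort:
        raise ValueError("empty cohort")

    out = Path(out_dir)
    subj_dir = out / "subjects"
    group_dir = out / "group"
    cmp_dir = out / "compare"
    for d in (subj_dir, group_dir, cmp_dir):
        d.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    static_nets = []
    jack_by_method = {meth: [] for meth in JACKKNIFE_METHODS}
    for ts in cohort:
        static_net, jack = _process_subject(ts, config, subj_dir, resume)
        static_nets.append(static_net)
        for meth in JACKKNIFE_METHODS:
            jack_by_method[meth].append(jack[meth])

    # cohort-level: sweep, consensus, reliable edges
    consensus = {}
    for meth in JACKKNIFE_METHODS:
        sweep = threshold_sweep(jack_by_method[meth], config.sweep_thetas)
        sweep.to_tsv(group_dir / f"sweep.{meth}.tsv")
        gr = group_analysis(
            jack_by_method[meth],
            theta=config.theta,
            subject_fraction=config.subject_fraction,
            null_value=config.null_value,
        ) if len(cohort) > 1 else None
        if gr is not None:
            consensus[f"jc_{meth}"] = gr.consensus
            rel = reliable_edges(gr, alpha=config.alpha)
            jio.write_edge_list(rel, group_dir / f"reliable.jc_{meth}.edges.tsv",
                                {"prevalence": gr.prevalence, "p_group": gr.p_group})
            jio.write_matrix_tsv(gr.prevalence, gr.roi_labels,
                                 group_dir / f"prevalence.jc_{meth}.tsv")
        else:
            consensus[f"jc_{meth}"] = retain_edges(
                jack_by_method[meth][0], config.theta
            )
    if len(cohort) > 1:
        consensus["static"] = group_consensus(static_nets, config.subject_fraction)
    else:
        consensus["static"] = static_nets[0]

    for name, net in consensus.items():
        jio.write_edge_list(net, group_dir / f"consensus.{name}.edges.tsv")
        write_brainnet(net, group_dir / f"consensus.{name}.node",
                       group_dir / f"consensus.{name}.edge")

    # pairwise method comparisons on the consensus networks
    pairs = [
        ("jc_pearson", "static"),
        ("jc_spearman", "static"),
        ("jc_pearson", "jc_spearman"),
    ]
    comparisons = {}
    for name1, name2 in pairs:
        rep = diff_report(consensus[name1], consensus[name2], name1, name2)
        stem = cmp_dir / f"{name1}_vs_{name2}"
        Path(f"{stem}.summary.txt").write_text(rep.summary() + "\n")
        labels = consensus[name1].roi_labels
        with open(f"{stem}.gained.tsv", "w") as f:
            f.write("roi_a\troi_b\themisphere\n")
            for i, j in rep.gained_edges:
                f.write(f"{labels[i]}\t{labels[j]}\t"
                        f"{classify_edge_hemisphere((i, j), labels)}\n")
        comparisons[f"{name1}_vs_{name2}"] = {
            "a": rep.table.a, "b": rep.table.b, "c": rep.table.c,
            "d": rep.table.d, "p_mcnemar": rep.p_mcnemar,
            "gained_tally": rep.gained_tally, "lost_tally": rep.lost_tally,
        }

    manifest = {
        "package": "jackfc",
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "subjects": [ts.subject_id for ts in cohort],
        "n_timepoints": [ts.n_timepoints for ts in cohort],
        "n_rois": cohort[0].n_rois,
        "edge_counts": {name: net.n_edges for name, net in consensus.items()},
        "comparisons": comparisons,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
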