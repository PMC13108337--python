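# jackfc

Jackknife-resampling functional connectivity for task-fMRI ROI time series.

Static functional connectivity (sFC) summarizes a whole BOLD run in a single
correlation matrix, so an edge whose significance hinges on a handful of
timepoints — suppressed or inflated by a transient artifact — is judged once,
on the full sample. `jackfc` implements the jackknife-correlation (JC)
alternative: for a series of T timepoints it recomputes the full R × R
correlation matrix T times, each time leaving one timepoint out, tests every
ROI pair in every iteration, and scores each edge by its **retention
fraction** — the share of iterations in which it was significant. Edges
retained in at least a threshold fraction θ (default 85%) of iterations form
the JC network. Because retention asks that significance survive *almost
every* perturbation of the sample rather than hold once on the whole of it,
the JC network recovers stable edges that the static test narrowly misses,
while discarding connections that depend on single timepoints.

The package is aimed at researchers analyzing parcellated fMRI (e.g. the
68-region Desikan-Killiany cortical atlas) who want an edge-stability
analysis without committing to sliding-window dynamics.

## The statistics

For each ROI pair the correlation (Pearson r or Spearman ρ) is tested
against zero with the standard two-tailed t-test,
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, and Fisher's
z = atanh(r) is recorded for reporting. Family-wise error over the
m = R(R−1)/2 unique pairs (m = 2278 for R = 68) is controlled by Bonferroni:
an edge is significant iff p·m < α (α = 0.05 by default).

* **Static network**: significant edges of the whole-series matrix (n = T).
* **JC network**: the same criterion applied inside each of the T
  leave-one-out iterations (n = T−1); an edge is kept iff it was significant
  in ≥ ⌈θ·T⌉ iterations.
* **Group level**: a consensus network keeps edges present in at least a
  fraction (default 85%) of subjects, and a one-sample two-tailed t-test
  checks each edge's per-subject retention fractions against chance-level
  retention (default 0.05). Edges passing both are "reliable".
* **Method comparison**: two networks on the same pair universe form a
  paired 2×2 detection table; the discordant counts b, c feed McNemar's
  exact test, p = min(1, 2·Σ_{k≤min(b,c)} C(b+c,k)·2^−(b+c)). Edge
  differences are tallied by hemisphere from the `lh_`/`rh_` label prefixes.

A synthetic-cohort generator draws subjects from a multivariate normal with
a planted correlation structure (plus optional single-timepoint outliers and
an optional AR(1) temporal coefficient), so the entire pipeline is testable
against known ground truth without any neuroimaging download.

## Worked example

```
jackfc simulate --n-subjects 3 --n-rois 8 --n-timepoints 50 \
    --planted-edges 2 --planted-r 0.7 --seed 2 --out sim
jackfc static sim/sub-0000.tsv --out static.tsv
# -> 2 significant edges (static pearson; alpha=0.05; bonferroni m=28; n=50)
jackfc jackknife sim/sub-0000.tsv --retention-out ret.tsv --edges-out jc.tsv
# -> 2 retained edges (jackknife pearson; alpha=0.05; bonferroni m=28; T=50;
#    theta=0.85 (cutoff 43 iterations))
```

Both planted r = 0.7 edges (and nothing else) are significant statically and
retained in ≥ 43 of the 50 leave-one-out iterations. Comparing the two edge
lists:

```
head -1 sim/sub-0000.tsv | tr '\t' '\n' > labels.txt
jackfc compare jc.tsv static.tsv --labels labels.txt
# paired comparison: jc vs static
# edge universe: 28 ROI pairs
# both: 2  only jc: 0  only static: 0  neither: 26
# exact McNemar p = 1
```

With no discordant detections the exact McNemar p is 1: on this clean
fixture the two methods agree. The full pipeline (per-subject networks,
threshold sweep, group consensus, all pairwise method comparisons, BrainNet
Viewer `.node`/`.edge` exports, and a run manifest recording every
threshold) is one command:

```
jackfc run sim/*.tsv --out runout
```

The same functionality is available as a library (`jackfc.jackknife_fc`,
`jackfc.retain_edges`, `jackfc.group_analysis`, `jackfc.diff_report`, ...);
see `docs/methods.md` for the model, parameter and design details.

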