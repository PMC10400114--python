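# funcnet

Weighted functional-connectome analysis for resting-state fMRI: from BOLD
volumes (or ROI time series) through whole-brain graph metrics to group
statistics — built for studies relating brain-network organisation to mild
traumatic brain injury (mTBI) history, lifetime incidence, and recency.

The scientific question the package addresses: does a history of repeated
concussion-level injury leave a measurable trace in the *organisation* of
the resting-state functional network, even when individual connections and
clinical presentation look normal? The analysis chain is the standard
threshold-free weighted construction:

1. **Confounds & QC** — framewise displacement (Power and Jenkinson
   formulations), standardized DVARS, tissue global signals, discrete-cosine
   high-pass (128 s), temporal/anatomical CompCor, expansion with
   derivatives and quadratics, and motion-outlier flags at 0.5 mm FD /
   1.5 standardized DVARS.
2. **Connectome** — mean BOLD in 4 mm spheres around ROI centres, Pearson
   correlation *r* between every ROI pair, Fisher transform
   *z* = arctanh(*r*), negative weights set to zero. No thresholding.
3. **Graph metrics** on the weighted matrix *W*:
   - global efficiency `E = (1/(n(n−1))) Σ_{i≠j} 1/d(i,j)` with lengths
     `1/w` (integration),
   - local efficiency: mean efficiency of each node's neighbour subgraph,
     cube-root weighted (segregation),
   - assortativity: Pearson correlation of endpoint strengths over edges
     (hub resilience; negative values mean vulnerable, widely distributed
     hubs).
4. **Group statistics** — Shapiro–Wilk-gated choice of pooled *t* /
   Wilcoxon rank sum for binary history, ANOVA / Kruskal–Wallis over
   ordinal incidence bins (0, 1–2, 3+) and recency categories, and OLS of
   assortativity on continuous incidence with age controlled by backwards
   elimination. All tests two-sided at α = 0.05.

A synthetic-data generator (`funcnet.synth`) produces ground-truth networks
with tunable assortativity, network-structured BOLD, 4D volumes, motion
traces, and full cohort tables, so every stage is testable end-to-end with
no data download.

## Worked example

Simulate a 60-subject cohort with the default planted contrast (group
assortativity targets −0.10 for controls vs −0.30 for injury history), run
the full pipeline and analysis plan:

```python
from funcnet.synth import CohortSpec, generate_cohort
from funcnet.stats import run_analysis_plan

cohort, truth = generate_cohort(CohortSpec(subjects_per_group=30, seed=7))
report = run_analysis_plan(cohort)

ac = report["metrics"]["ac"]
print(ac["normality"]["classification"])      # normal
print(ac["history"]["name"],                  # two_sample_ttest
      round(ac["history"]["statistic"], 2),   # -2.5
      round(ac["history"]["p_value"], 4))     # 0.0153
print(round(report["metrics"]["ge"]["history"]["p_value"], 3))  # 0.905
```

The assortativity coefficient is normally distributed across subjects, so
the history comparison runs as a pooled t-test: t₅₈ = −2.50, P = 0.015 —
the history group's networks are measurably less assortative (less
resilient hubs), recovering the planted effect. Global efficiency, where
nothing was planted, shows no difference (P = 0.905). The regression block
of the same report relates continuous lifetime incidence to assortativity
with age eliminated as a non-significant covariate, and its standardized
coefficient satisfies |β| = √R² exactly for the single-predictor model.

The same analyses are available from the shell:

```bash
funcnet simulate --seed 7 --out-dir sim/
funcnet stats sim/cohort.csv --out report.json
funcnet connectome sub-01_bold.nii.gz --roi-table rois.tsv --out sub-01_conn.tsv
funcnet metrics sub-01_conn.tsv --out metrics.csv
```

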