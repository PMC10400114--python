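# Methods

`funcnet` implements a whole-brain weighted functional-connectome analysis
for resting-state fMRI: per-frame nuisance confounds, subject-level
connectome construction, weighted graph metrics, and group statistics
relating those metrics to mild-traumatic-brain-injury (mTBI) covariates.
A synthetic-data generator produces every input the pipeline consumes, so
the full chain is testable without any scan data.

## Connectome construction

The BOLD signal is averaged over voxels whose centres fall within a closed
4 mm ball around each ROI centre (world coordinates via the NIfTI affine;
voxels outside the brain mask excluded). Pairwise Pearson correlations are
Fisher z-transformed (arctanh, with |r| clipped at 1 − 10⁻⁷), negative
weights are set to zero, and the diagonal is forced to zero. No sparsity or
correlation-strength thresholding is applied at any stage; all downstream
metrics operate on the weighted matrix, whose entries may exceed 1.
Zero-variance ROI columns yield zero rows with a logged warning rather than
aborting the subject. Incidentally, because arctanh fixes 0 and preserves
sign, z-transforming before or after zeroing negatives gives identical
numbers; the stage tags nonetheless enforce the declared z-then-zero order.

## Graph metrics

Edge weights map to lengths by the reciprocal, the standard convention for
efficiency measures. All-pairs distances use Dijkstra's label-setting
algorithm; unreachable pairs contribute zero efficiency (1/∞ = 0), which
keeps global efficiency bounded and monotone in the weights.

- **Global efficiency (GE)** — mean inverse shortest-path length over
  ordered node pairs.
- **Local efficiency (LE)** — weighted formulation with cube-root
  weighting: for node *u* with neighbours V and degree k ≥ 2,
  E_loc(u) = (1/(k(k−1))) Σ_{j≠h∈V} (w_uj w_uh)^{1/3} / d′_jh, where d′ is
  the shortest path inside the neighbour subgraph on lengths (1/w)^{1/3}.
  Two executable anchors pin this variant: on 0/1 weights it reduces
  exactly to binary local efficiency, and on a unit-weight complete graph
  every node scores 1. Nodes with degree < 2 score 0.
- **Assortativity coefficient (AC)** — Pearson correlation between the
  node strengths (weighted degrees) at the endpoints of each edge, every
  undirected edge contributing its pair symmetrically. A binary-degree
  variant is available behind a flag for sensitivity analysis. On regular
  graphs the endpoint variance is zero and the coefficient is returned as
  an explicit undefined marker (`None`), never silently 0.

All three are verified against brute-force oracles (Floyd–Warshall,
explicit neighbour-subgraph enumeration, explicit edge enumeration) on 200
seeded random graphs with n ≤ 12, and against independent binary
implementations on 0/1 graphs.

## Confounds

- **Framewise displacement** — Power: absolute sum of relative motions,
  rotations converted on a 50 mm sphere (field standard). Jenkinson: RMS
  displacement under the relative affine, integrated over a solid sphere of
  radius 80 mm (the original formulation's default), closed form
  √(R²/5 · tr(AᵀA) + |b|²). First frame 0 by convention.
- **DVARS** — RMS over in-mask voxels of the backward temporal difference,
  standardized by dividing by its median over non-initial frames (median 1
  by construction). This simple robust scaling stands in for pipelines'
  autocorrelation-based standardizations, whose exact form is not uniquely
  defined; the outlier threshold is configurable alongside it.
- **High-pass filter** — least-squares projection removing the constant and
  every DCT-II basis function with period above the 128 s cutoff;
  idempotent by construction.
- **CompCor** — temporal variant selects the top 2% of in-mask voxels by
  temporal SD (ties broken by linear voxel index for determinism);
  anatomical variant thresholds probabilistic tissue masks at 0.99.
  Components are unit-normed left singular vectors of the demeaned voxel
  matrix, sign-fixed so each component's largest-magnitude voxel loading is
  positive; components are retained up to 50% cumulative squared-singular-
  value share.
- **Outliers** — frames strictly exceeding 0.5 mm FD or 1.5 standardized
  DVARS are flagged; flags annotate, nothing is scrubbed or deleted.

## Group statistics

Outcomes are gated by a Shapiro–Wilk test at α = 0.05 (Q–Q plot coordinates
are emitted for inspection but never gate automatically). Binary history
comparisons use the pooled-variance t-test (normal) or the Wilcoxon rank
sum with midranks, tie-corrected variance and continuity correction
(non-normal; the z statistic of the normal approximation is reported).
Lifetime incidence is binned ordinally (0, 1–2, 3+) and compared by
one-way ANOVA or Kruskal–Wallis with tie correction, as are the three
recency categories. Continuous incidence is regressed on the assortativity
coefficient by OLS with age controlled via backwards elimination
(removal threshold 0.05, configurable; the predictor is never removed).
For a single-predictor final model the standardized coefficient satisfies
|β| = √R² to 1e−12 — an identity the suite asserts on its own fits.
(A published pair of values this package emulates, β = 0.20792 with
R² = 0.0432, differs from that identity in the 4th decimal, a rounding
artefact of the source report.) Printed percentages use two decimals,
half-away-from-zero, matching frequency tables of the 46.05/53.95 form.
Missing counts are excluded listwise per analysis. Degenerate-variance
failures are surfaced as structured error entries in the report.

## Synthetic-data generator

Defaults emulate the reference study design at desk scale: two groups of
30 subjects, 265 frames at TR 2.3 s, 40-node ground-truth networks, group
assortativity targets −0.10 (control) vs −0.30 (history), ages normal at
31.9 ± 3.7 / 34.1 ± 4.5 years, lifetime counts 1 + Poisson(2.3) (median 3),
~2.5% missing counts, recency sampled at the 8/12/51/11 proportions.

Networks are Erdős–Rényi-style draws with uniform (0.2, 1.0) weights,
bridged to connectivity, then driven to the target assortativity by
degree-preserving double-edge swaps accepted only when they move the
coefficient strictly toward the target (tolerance 0.05, capped
iterations). The network maps to a correlation matrix Σ = I + c·W
(coupling c = 0.6), with diagonal loading and renormalization whenever the
construction is not positive definite; this keeps the edge-weight →
correlation relationship monotone. BOLD series are multivariate-normal
draws plus independent observation noise (SD 0.3 of the unit-variance
signal). Optional 4D volumes paint each ROI's series onto disjoint 4 mm
spheres; motion traces are low-amplitude random walks with level-shift
spikes so the flagged-frame fraction tracks the spike probability.

**Edge density 0.35 (calibrated).** The estimated connectome is dense —
every pair with a positive sample correlation becomes an edge — and the
edge-count-based assortativity coefficient is therefore diluted by
spurious weak edges in proportion to the ground-truth sparsity. At density
0.15 the planted contrast is attenuated below reliable detectability at
265 frames; at 0.35 (also the more realistic regime for threshold-free
positive-weight functional networks) the planted −0.30 vs −0.10 contrast
yields a standardized group difference around 1.4 and is detected in ≳90%
of seeded cohorts. This calibration was fixed once, before the test suite
was frozen.

**Known estimator bias.** For the same reason, the estimated AC does not
converge to the ground-truth AC as frames grow: at any finite scan length
about half the true non-edges carry small positive sample correlations
and enter the edge list, so the estimator converges to a diluted limit.
The suite therefore asserts consistency toward the estimator's own
large-frame limit (monotone decreasing median error over 100 → 265 → 1000
frames), and tracks ground truth through the correlation between
per-subject mean estimates (over replicate scans) and true AC (r > 0.7).
Passing tests consequently show that the pipeline orders and separates
subjects by network resilience, not that the absolute AC value is
unbiased — the same caveat applies to real data.

What the generator does not model: hemodynamic response, physiological
noise spectra, scanner drift or artefacts, spatial autocorrelation of
noise, or any true link between covariates (age, count) and network
structure beyond the group-level targets.

## Numerical conventions

Symmetry is enforced to 1e−10 and sub-tolerance asymmetry averaged away;
|r| is clipped at 1 − 10⁻⁷ before arctanh; constant columns are detected
with a relative tolerance (sd ≤ 1e−12·max(|x|, 1)); component retention
uses a 1e−12 slack so exact-share ties (e.g. four equal components at a
0.5 target) resolve to the smaller count; rank statistics use midranks.
All generators are deterministic given a seed (NumPy `SeedSequence`
spawning); pipeline outputs carry provenance sidecars without timestamps
so reruns are byte-identical.

## Problem sizes used in the shipped checks

Oracle sweeps use 200 random graphs with n ≤ 12; cohort power uses 100
replicate cohorts at the default 30/group; type-I calibration uses 1000
replicate cohorts at 10/group (the rate is size-free, and the smaller
cohorts keep the check cheap); recovery uses 20 subjects × 8 replicate
scans. A 300-node connectome smoke test is intentionally omitted from the
default suite; the metrics scale as ordinary dense Dijkstra runs and the
40-node scale exercises every code path.

## Limitations

- The statistical plan mirrors a single-site cross-sectional design: no
  multiple-comparison correction, no site harmonization, no mixed models.
- The DVARS standardization is a documented stand-in (see above).
- "General linear models" for normally distributed categorical contrasts
  are implemented as one-way ANOVA over bins rather than regression on
  ordinal codes; the choice is visible in the report output.
- Confound regression out of ROI series is available but off by default;
  the default pipeline computes confounds for QC annotation only.
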