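# Methods

## The prediction problem

`pathrisk` predicts censored survival (or recovery) risk from gene
expression profiles. The input is a genes × samples matrix of
expression indices (already log-scaled and normalized upstream), a
per-sample right-censored outcome (time, event), and one or more
collections of gene sets (pathways, regulons, positional bands) in GMT
format. The output is a per-sample risk score: higher score, shorter
expected survival.

The method treats *gene sets* and *single genes* as one pooled feature
family. Gene sets are summarized into expression indices; single genes
ride through the same machinery as pseudo gene sets with one member.
This hybrid pool hedges against incomplete pathway annotation: signal
carried by genes that belong to no annotated set can still enter the
predictor.

## Gene-set summarization (maxmean)

For gene *i* and sample *j*, let e'_ij be the expression standardized
per gene to mean 0, SD 1 (sample SD, n−1 denominator; parameters always
estimated on training samples only). For gene set *g* with N_g member
genes present in the matrix,

    u_gj = absmax[ (1/N_g) Σ (e'_ij)+ , (1/N_g) Σ (e'_ij)− ]

where (x)+ / (x)− are the positive/negative parts and absmax keeps the
argument of larger magnitude. The summary responds to a coherent up- or
down-shift of the set's members without letting opposite-signed members
cancel. u_g is then restandardized across training samples and rescaled
to the *averaged* moments of its members:

    x_gj = u'_gj · sqrt( (1/N_g) Σ σ_i² ) + (1/N_g) Σ μ_i .

Two consequences are enforced exactly and tested to machine precision:
on training samples each set feature has mean = average member mean and
variance = average member variance; and a one-member set reproduces the
raw gene, so single genes and gene sets are exchangeable feature types.

Numerical details: N_g counts members present after intersecting with
the matrix (absent genes contribute no measurement); constant genes are
removed before any summarization; sets whose summary has zero training
variance are dropped; the absmax tie (both arguments 0) returns 0. The
u-standardization parameters are stored from training and reused on
test samples — the predictor never touches test statistics.

## Feature screening (Cox score)

Each feature is scored by the standardized score test of the Cox
partial likelihood at β = 0:

    s = U(0) / sqrt(I(0)),

U(0) = Σ over event times of (x_event − risk-set mean), I(0) = Σ of
risk-set variances, Breslow convention for ties. Under the null s is
asymptotically N(0, 1) (verified by KS test in the suite), so |s| is
comparable across feature kinds and is what selection thresholds.

## Threshold selection by cross-validation

The |score| threshold is chosen by repeated stratified 3-fold CV inside
the training set (default 100 repeats). Candidate thresholds are 20
evenly spaced quantiles of the full-training |score| distribution from
the 50th to the 99th percentile — scale-free and bounded in cost. For
each fold and threshold the entire pipeline (standardization, feature
building, scoring, selection, weighted PC fit) is refit on the 2/3 and
the held-out 1/3 is scored by the Cox likelihood-ratio statistic of its
predicted risk; the threshold with the best mean held-out performance
wins, ties toward the larger threshold (parsimony). Folds are
stratified by event status so every fold carries events; all repeats
derive from one RNG seed and the search is bit-reproducible.

Inside CV the PC orientation step is skipped: the held-out metric is
invariant to a sign flip of the risk score.

## The membership-weighted PC predictor

Selected features are centered at their training means and stacked into
the weighted matrix diag(N_1..N_k)·[x_1ᵀ; …; x_kᵀ]. The first
right-singular direction gives the per-sample predictor score and the
loading vector; with all N_i = 1 this is exactly conventional PCA
(tested against an independent SVD at 1e-10). The weights emphasize set
features summarized from more members. Because the PC sign is
arbitrary, the predictor is oriented so the training Cox coefficient of
the score is non-negative (higher score = higher risk). Risk for a new
sample is the projection of its rebuilt, centered, weighted feature
column on the loading.

A consequence of the N_i weighting worth knowing: single-gene rows
enter the PC with weight 1 against N_i ≈ 10–30 for sets, so their
influence scales like 1/ΣN_i² whenever set features are selected. The
hybrid pool therefore behaves like the geneset-only predictor plus a
small refinement from the gene rows, and the hybrid-vs-geneset-only
performance difference is structurally small (a few 0.001 of C in our
experiments); the hybrid-vs-single-gene difference is larger. A
`sqrt_members` weighting is available as a clearly non-default variant.

## Evaluation statistics

Four statistics per (risk, survival) pair: the Cox likelihood-ratio
statistic (Breslow ties; Newton fit with step halving, β capped at 15
on the standardized scale so monotone likelihoods — e.g. a perfect-rank
risk with no censoring — return a finite, large LR instead of
diverging); Harrell's C (usable pairs, risk ties = 1/2); R² in the
Cox–Snell form 1 − exp(−LR/n), chosen because it is computable from the
reported LR and bounded in [0, 1); and the two-sample log-rank p after
a median-risk split (ties at the median go to the low-risk group —
arbitrary but fixed).

The LR fit is hand-written because the Breslow convention is needed for
internal consistency with the score test (the installed Cox fitters use
Efron ties); it is cross-checked against lifelines on tie-free data
where the two conventions coincide. Harrell's C and the log-rank test
are delegated to lifelines and cross-checked against brute-force
oracles in the suite.

## The synthetic cohort generator

The generator produces the structure the method assumes, nothing more:

* Every pathway — informative, decoy, and "orphan" — is a disjoint
  co-expression module: member genes load on the module's latent factor
  (e = loading·f + noise, unit total variance; default loading 0.3,
  i.e. within-set correlation 0.09, individually weak member genes).
* Hazard-linked factors (informative sets plus orphan pathways) share a
  common severity axis with pairwise correlation 0.5; decoy-module
  factors are independent of it. The per-sample log-hazard is the
  normalized factor sum, scaled so `beta_factor` (default 1.0) is the
  log-HR per SD of the aggregate pathway signal. A graded-signal mode
  (`beta_factor_sd`) draws one coefficient per factor instead.
* Orphan signal: a fraction of signal genes (default scenario 0.3)
  belongs to pathways that drive the hazard but are absent from the
  annotated collection — annotation incompleteness at the pathway
  level. Standalone direct-effect orphan genes are also available.
* Survival is exponential with rate baseline·exp(η); independent
  exponential censoring has its rate solved (Brent) so the expected
  censoring fraction equals the target (default 0.3).

These choices encode three facts about real cohorts that matter for the
method's comparative claims: prognostic pathways co-vary along a
severity axis (otherwise no single principal component can represent
the hazard); transcriptomes contain strong non-prognostic co-expression
modules (otherwise "select liberally and average everything" is
unbeatable and feature selection is pointless); and member genes are
individually weak relative to their pathway aggregate (the regime that
motivates set summaries). What the generator does **not** emulate:
platform/probe-level noise, batch effects, heavy-tailed expression,
overlapping pathway membership, non-proportional hazards. Passing tests
therefore demonstrate internal correctness and the method's qualitative
behaviour in its intended regime, not performance on any real cohort.

Defaults mirror a trauma-cohort-scale study: 150 training samples, 200
candidate pathways of 8–15 genes with 5 informative, ~30% censoring.

## Experiment scales

The standing experiments (`pathrisk.experiments`, run by both the test
suite and `scripts/acceptance.py`) use deliberately desk-scale setups
chosen once:

* null calibration: 200 no-signal cohorts (100 train / 100 test, 40
  modules), CV with 10 repeats per cohort;
* planted-pathway recovery: 20 cohorts at generator defaults, CV with
  20 repeats;
* mode comparison: 20 cohorts, 100 modules with orphan fraction 0.3,
  test cohorts of 400 samples (validation sets of several hundred are
  typical of the field) and CV with 20 repeats, to keep measurement
  noise below the small paired C differences being detected;
* split robustness: 20 graded-signal cohorts (40 modules, all carrying
  N(0, 0.15) hazard coefficients, loading 0.5) — at sparser signal the
  rank-reliability of *both* feature kinds is indistinguishable from
  noise and the comparison is uninformative.

The pipeline's own defaults keep 3 folds × 100 repeats; the reduced
repeat counts inside Monte-Carlo loops only widen the threshold-choice
noise, which the experiments absorb in their replicate counts.

## Known limitations

* The single-PC predictor represents one latent risk direction; hazards
  spread over several uncorrelated axes are invisible to it by design.
* The N_i weighting makes single-gene features nearly inert whenever
  sets are selected (see above); this is faithful to the published
  method, not a defect of the implementation.
* The maxmean summary is slightly less efficient than a plain member
  mean at recovering a module factor (~0.04–0.06 correlation in our
  measurements); it is retained because it is the published statistic.
* Monotone partial likelihoods are reported at the β cap rather than as
  errors; LR values above ~200 should be read as "separation", not as
  calibrated statistics.
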