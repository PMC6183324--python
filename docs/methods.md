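# Methods

## The decision model

The package implements the Analytic Network Process for one prioritization
problem: weighing shift-work disorders. Decision elements live in three
clusters — 7 disorder criteria, 20 complaint sub-criteria (each owned by a
criterion), 3 shift alternatives — under a single goal. A *comparison
context* is a target element together with the cluster-mates compared
"with respect to" it; every context elicits one positive reciprocal
judgment matrix on the Saaty scale and yields one local priority vector
(the normalized principal right eigenvector).

### The dependency structure is an assumption

The source study describes its network only as a figure; the exact edge
set is not enumerated. The bundled network therefore encodes a documented,
overridable default: the full hierarchy (goal → criteria → sub-criteria →
alternatives) plus inner dependence among the criteria (each criterion's
column also receives a comparison of the other six criteria). Users can
disable the feedback (`load_shiftwork_network(criteria_feedback=False)`)
or supply an explicit `edges:` list. With feedback on, a respondent faces
35 contexts (206 judgments); the pure hierarchy needs 28 (101 judgments).

## Pairwise machinery

- **Scale.** 17 admissible values `1/9 … 1/2, 1, 2 … 9`. The odd integers
  carry verbal anchors; even intermediates are accepted, as is standard,
  and the full 17-value set is also what the random-index simulation
  draws from.
- **Priorities.** Power iteration, uniform start, L1 normalization each
  step, tolerance 1e-12 on the max-norm of successive iterates, cap
  10,000 iterations. `λ_max` is the mean of `(A w)_i / w_i`. Positive
  matrices have a unique positive principal eigenvector, so the method is
  globally convergent; tests verify agreement with a dense
  eigendecomposition to 1e-8 on hundreds of random matrices.
- **Consistency.** `CI = (λ_max − n)/(n − 1)`; defined 0 for `n ≤ 2`
  (all 2×2 reciprocal matrices are consistent). `CR = CI/RCI(n)` with a
  strict acceptance rule `CR < 0.1`; a CR equal to the boundary up to
  machine rounding is rejected (the quotient 0.052/0.52 must not slip
  under the threshold through float error).
- **Random consistency index.** `estimate_rci(n, samples, seed)` draws
  upper-triangle entries i.i.d. uniformly from the 17-value grid,
  reciprocal-fills, and averages CI via batched power iteration. This
  discrete-uniform dialect reproduces the tabulated row
  (0, 0, 0.52, 0.89, 1.11, 1.25, 1.35, 1.40, 1.45, 1.49) within ±0.01 at
  large sample sizes, unlike continuous schemes that give 0.58 at n = 3.
  The tabulated values ship as a data file and back CR for n ≤ 10; larger
  orders require a simulated index passed explicitly.

## Group aggregation and screening

Respondents are screened whole: one matrix with `CR ≥ 0.1` excludes the
respondent (per-matrix screening is available). Survivors are pooled per
context by the entrywise geometric mean of judgments (AIJ), computed in
the log domain on the upper triangle so reciprocity is preserved exactly;
aggregates may leave the 17-value grid but stay within `[1/9, 9]`.
Mean-of-eigenvectors (AIP) is provided as an option. AIJ before
prioritization is the default because the groups are homogeneous cohorts;
the source study does not state its pooling method.

## Supermatrix and synthesis

Cell (row = source, column = target) of the unweighted supermatrix holds
the source's local priority with respect to the target; the goal is not a
supermatrix node. Cluster weights (uniform by default — the study never
published cluster-level judgments; pairwise cluster weights can be
supplied) scale the blocks so each nonzero column sums to 1, renormalized
per column over the clusters actually present there. Sink nodes
(alternatives) get a self-loop of weight 1 by default, making the chain
absorbing; `leave_zero` is available.

The limit is computed by repeated squaring with entrywise tolerance 1e-10
(cap 2^64-equivalent powers). A squaring fixed point that is not
stationary under the original matrix signals periodicity; the Cesàro
average over one detected period (cap 48) is returned, which is the
correct limit for cyclic stochastic chains (a pure 2-cycle averages to
uniform). Squaring reaches the same limit as the odd-power prescription
for aperiodic matrices in logarithmically many multiplications.

Because the hierarchy-with-absorbing-alternatives limit puts all mass on
the alternatives, reported weights are synthesized as follows: criterion
weights are the goal-context priorities; sub-criterion weights are
reported local to their parent (summing to 1, the published presentation;
global weights = criterion × local are available); alternative weights
push the goal priorities through the limit matrix
(`global_alternative_weights`), which on a feedback-free network equals
the closed-form weighted-sum composition to 1e-8 (tested). For limits
with mass in every cluster (irreducible networks, pseudo-limit fixtures)
`extract_priorities` renormalizes the limit column per cluster directly.

The desirability index `D_i = Σ_j Σ_k P_j A^D_kj A^1_kj S_ikj` is
computed alongside; with no sub-criterion interdependence judgments the
dependency factor `A^D` defaults to 1, making `D` the hierarchical
composition, and the limit route and `D` then agree in value and rank
(tested). The alternative count is data-driven (the formula is often
written with four alternative terms; this study has three shifts).
Reports round to 3 decimals (round-half-even) in rendered tables and keep
full precision in JSON; identical config and seed give byte-identical
JSON.

## Synthetic cohorts

The generator emulates the study design: groups `nurses_8h`,
`support_12_24`, `security_24_48` of 100 respondents each (300 total).
Ground truth defaults to the published group weights interpreted as true
context priorities; contexts the tables do not cover are filled by two
documented conventions — criteria-feedback contexts reuse the criterion
weights restricted to the compared six and renormalized, and an
alternative omitted from a printed ranking (the support group's evening
shift) enters at the scale's extreme ratio, 1/9 of the leader, before
renormalization. A respondent's matrix for truth `w` is
`a_ij = (w_i/w_j) · exp(ε)`, `ε ~ N(0, σ²)` i.i.d. on the upper triangle,
clipped to `[1/9, 9]`, snapped to the nearest admissible value,
reciprocal-filled. Default `σ = 0.15`: moderate judgment noise under
which a group of 100 recovers the true criterion rank order essentially
always (50/50 seeded replicates in the calibration test) while individual
7×7 matrices are usually measurably inconsistent. Each group has its own
random stream derived from the master seed and the group label, so
reseeding one group leaves the others bit-identical. Demographics
reproduce the published sample margins (72% married, 82% obligatory shift
selection, 62% satisfied; age and experience bands) as independent draws
and are metadata only.

### What the generator does and does not emulate

It reproduces the cohort sizes, the Saaty-scale granularity of real
questionnaires, reciprocal structure, and inconsistency levels that rise
with matrix order and noise. It does not model respondent heterogeneity
beyond i.i.d. log-normal noise, within-respondent correlation across
contexts, demographic dependence, or the disorders themselves. Passing
recovery tests therefore show the *pipeline* is correct and
well-conditioned at the study's design size — not that the published
weights are themselves reproducible, since the raw judgments were never
released.

### Snap bias

Scale-snapping is a deterministic distortion, not noise: at σ = 0 each
entry moves at most half the gap between adjacent admissible values, and
aggregation cannot average it away. Consequently recovery error decreases
monotonically in cohort size only for ground truths whose ratios lie on
the grid (tested with such a truth: median max-abs error 0.006 → 0.003 →
0.002 at n = 5/25/100); fixture-derived truths plateau at a snap-bias
floor of roughly 0.015 regardless of cohort size. Near-ties in the
published weights (e.g. the support group's personal-life 0.167 vs mental
0.164) sit inside that floor, which is why synthetic runs occasionally
swap exactly those neighbours while wide gaps are always recovered.

## Published-weight fixtures

The three groups' printed criterion, sub-criterion and alternative
weights are transcribed at the printed 3-decimal precision and used as
(a) generator ground truth and (b) comparison targets. Loading attaches
warnings — never errors — where printed families do not sum to 1 beyond
rounding (tolerance 0.005): notably the security group's alternative
weights sum to 1.26 as printed, and the support ranking omits the evening
shift. The security table's group header repeats "second group" in print;
the fixture keys by shift pattern. Delta tables
(`compare_to_published`) cover exactly the printed cells and report rank
agreement over shared keys.

## Problem sizes and determinism

Default analysis runs use the full study design (3 × 100 respondents);
test-suite pipeline runs use smaller cohorts (5–20 per group) and
calibrated Monte-Carlo sizes (500–50,000 random matrices; 20–50
replicates), chosen so the whole suite exercises every path at
interactive speed. All randomness flows through numpy `SeedSequence`
spawning from named seeds; no step reads clocks or global state.

## Known limitations

- The dependency structure beyond the hierarchy is an assumption; results
  with feedback on are conditional on that default.
- Cluster weights default to uniform in the absence of published cluster
  judgments.
- No fuzzy extensions, no alternative prioritization methods beyond the
  eigenvector (the geometric-mean/LLSM route is not implemented), no
  missing-judgment completion, and no benefits/opportunities/costs/risks
  multi-network merging.
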