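# Methods

## Statistical model

The pipeline treats gene expression as acting on survival through
*thresholds*: for gene g with signal x_g and cutpoint c_g, the hazard of
a patient is proportional to exp(β_g · 1[x_g > c_g]). Screening,
scoring and validation all operate on this dichotomized scale; no
continuous-covariate Cox models are fit for genes.

### Survival kernel

Kaplan–Meier estimation, the two-group log-rank test, Cox proportional
hazards and Pearson chi-square tests are implemented directly:

* **KM**: product-limit over distinct event times; a patient censored
  exactly at an event time remains in the risk set at that time. The
  median is the smallest t with Ŝ(t) ≤ 0.5; `NOT_REACHED` (∞) when the
  curve never drops that far.
* **Log-rank**: z = (O₁ − E₁)/√V with the hypergeometric variance
  V = Σ_t d_t (n₁t/n_t)(1 − n₁t/n_t)(n_t − d_t)/(n_t − 1); χ² = z²
  against χ²₁, two-sided.
* **Cox**: Newton–Raphson on the log partial likelihood with
  step-halving, gradient max-norm tolerance 1e−9, 50-iteration cap;
  Efron tie correction by default, Breslow available (and used
  internally for the score-test/log-rank equivalence, which holds
  exactly for a binary covariate without tied event times). Covariates
  are standardized internally for conditioning and back-transformed.
  Monotone likelihood (separation) is flagged as `converged=False` —
  both when iterations exhaust and when the standardized coefficient
  exceeds 10, since the gradient also vanishes as β̂ runs away.
  Standard errors come from the inverse observed information; Wald
  p-values are two-sided.
* **Chi-square**: Pearson, no continuity correction, df = (r−1)(c−1);
  zero margins are rejected rather than patched.

### Maximally selected rank statistics

Candidate cutpoints are the distinct observed marker values whose
left-group fraction ε lies in [minprop, maxprop] (defaults 0.1/0.9, the
usual maxstat convention). Two standardizations coexist by design:

* the **hypergeometric log-rank z** (identical to `logrank_test`) is
  what the scan reports and what `maxstat_select` maximizes — every
  candidate is interchangeable with an explicit two-group test, and the
  brute-force oracle in the test suite exploits exactly that;
* the **rank-score z** sums the centered log-rank (Nelson–Aalen) scores
  a_i = δ_i − Ĥ(t_i) over the left group and standardizes by the exact
  permutation variance m(n−m)/(n(n−1))·Σa². Under permutation of the
  marker, this process over ε has exactly the Brownian-bridge
  covariance, which is what the analytic null describes. All p-values
  (analytic and permutation) refer to this maximum; the two maxima
  differ at O(1/n) and select the same cutpoint in practice.

`ls_approx` computes P(max_j |B(t_j)|/√(t_j(1−t_j)) > M) over the actual
candidate fractions by mapping the bridge to a Brownian motion and
propagating the corridor-survival density with Gaussian transition
kernels on a trapezoid grid (81 points; candidate sets denser than 80
fractions are thinned quantile-wise). The integration was validated to
±0.001 against a 4×10⁵-draw Gaussian Monte Carlo. The closed-form
improved-Bonferroni bound φ(M)(M−1/M)·log(ε₂(1−ε₁)/(ε₁(1−ε₂))) + 4φ(M)/M
serves as a tail shortcut (returned when it is below 1e−5) — used alone
it overstates mid-range p-values by ~0.1. `naive_logrank` returns the
unadjusted χ²₁ tail of the selected split and is anti-conservative; it
is provided because published gene tables are sometimes computed that
way. The analytic p is floored at the naive p, so the selection penalty
never vanishes.

**Known accuracy limits.** At n = 50 the permutation null of the maximum
deviates from the asymptotic bridge by up to ~±0.02 in the mid/high-p
range (a finite-population CLT effect, present even for normally
distributed scores and therefore not removable by skewness
corrections); in the decision-relevant tail (p < 0.05) agreement is
within ~0.003. The permutation oracle exploits the fact that permuting
the marker leaves candidate left-group sizes unchanged, so each
permutation is a prefix-sum over re-ordered scores — n_perm = 10⁴ costs
milliseconds.

### Screening and selection

Each probe is scanned against OS and EFS; the hazard ratio reported per
endpoint comes from a univariate Cox fit of the indicator 1[x > c*] at
the selected cutpoint. Benjamini–Hochberg adjustment is applied within
endpoint across the screened panel (m = number of probes). A probe is
called prognostic only when FDR ≤ α on both endpoints; the direction is
BAD when both HRs exceed 1, GOOD when both are below 1, and discordant
probes are dropped (a config switch relaxes concordance, in which case
the OS direction decides). Records are ranked by OS FDR.

### Score construction and use

Weights default to w_g = ln HR_g from the OS dichotomized Cox fit.  The
log scale is the package's deliberate choice: with raw hazard-ratio
weights a protective gene (HR < 1) above its cutpoint would still *add*
a positive term, breaking the monotonicity "higher score = worse
prognosis"; log weights also give the packaged 22-gene panel a
theoretical range of ±24.06, consistent with that panel's published
observed cohort range (−22.45 to +21.59), where raw-HR weights would
give ±58.5. A `weight_scale="hr"` fidelity mode is retained. The
boundary rule is strict: expression exactly at the cutpoint contributes
−w. Genes annotated to several pathways contribute once to the global
score and once to each of their pathway sub-scores; a single-gene
sub-panel (the BER case in the packaged panel) is allowed but reported
as such.

The score-level cutoff is the maxstat-selected cutpoint of the score
against OS under the same admissibility bounds as gene screening; in
validation mode the cutoff and panel are frozen inputs and no search is
performed. The t(4;14) and del17p expression surrogates (MMSET spike
above / TP53 below a threshold) have **no default thresholds** — they
are platform- and cohort-calibrated numbers the caller must supply.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes
about a bulk-microarray myeloma cohort:

* **Expression**: i.i.d. log-normal per probe, location log 500 and
  scale 1 by default, giving non-negative right-skewed signals with
  median in the hundreds, like MAS5 summaries under a global scaling
  factor. Probes are independent by default.
* **Survival**: death hazard h_os·exp(Σ_g β_g·1[x_g > c_g]) with c_g at
  a configured quantile of the probe's distribution; progression adds
  an extra baseline under the same linear predictor; the EFS event is
  the first of progression or death, so EFS ≤ OS holds per patient.
  Censoring is exponential and independent, with an optional
  administrative cap; times are rounded to 0.1 month (floor 0.1).
* **Canonical configuration** (`canonical_config`): 84 probes, 22
  effect genes mirroring the published panel's composition (17 adverse,
  5 protective), hazard-ratio magnitudes geometrically spread over
  [1.8, 4], thresholds between the 30th and 70th percentiles. The
  baseline death rate is solved numerically so the *cohort-level*
  median OS is ≈ 60 months (typical of newly-diagnosed myeloma cohorts
  of the microarray era; the uncentred heavy-tailed linear predictor
  makes the baseline alone uninformative); censoring rate 0.012/month
  with a 120-month cap, progression baseline 1.6× the death baseline.
  At n = 300 this yields ≈ 41% observed OS events.

**What passing tests do and do not show.** Because the 22 effects are
simultaneous and independent, the linear predictor's variance is ≈ 5,
and each gene's *marginal* dichotomized hazard ratio attenuates to
≈ 1.2–1.8 — far below its conditional β. Selection-adjusted screening
therefore recovers only the strongest fraction of the panel (sensitivity
≈ 0.2 at n = 300) while keeping false discoveries at zero; the naive
p-method roughly triples sensitivity at the cost of several false
discoveries. This attenuation is a property of the generative design
(real repair genes are co-expressed, concentrating the same prognostic
signal in fewer effective dimensions), so synthetic sensitivity numbers
do not translate to real cohorts; what the synthetic results *do*
establish is correct null calibration, correct cutpoint localization
(quantile error ≈ 0.06), and that a frozen panel + cutoff transfers to
independent cohorts (log-rank p < 0.05 in 50/50 replicates).

## Numerical and design choices

* Ties in Cox fits: Efron by default; published-style gene tables use the
  dichotomized HR at the selected cutpoint, never a continuous fit.
* Scan tie-break: among equal |z|, the smallest cutpoint wins
  (deterministic outputs).
* Proportions in reports are printed to one decimal; p-values in
  scientific notation with two significant digits.
* Readers reject malformed input (duplicate ids, negative signals,
  non-binary events, non-positive times) with the offending row or
  column named, rather than coercing.
* Expression values missing for a panel probe raise by default;
  `missing="drop"` omits the gene with its weight (a documented
  non-standard fallback for cross-platform panels).
* All simulation entry points take explicit integer seeds;
  `run_train`/`run_validate`/`run_simulate` write a manifest (config
  hash, seed, outputs) sufficient to reproduce a run byte-for-byte
  (plots excluded).

## Limitations

* No time-dependent covariates, stratified Cox, competing risks or
  frailty models.
* The synthetic generator has no probe–probe correlation by default and
  no copy-number/translocation structure; its EFS definition (first of
  progression or death) is a simulation convention.
* MAS5 normalization itself, .CEL parsing, and externally published
  risk scores (UAMS-HRS, IFM, GPI, RS) are out of scope; the latter are
  consumed as precomputed clinical columns in Cox comparisons.
* The Brownian-bridge p-value is asymptotic; at n ≲ 50 its mid-range
  values carry the ±0.02 finite-sample deviation quantified above.
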