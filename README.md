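# drscore

**Gene-expression prognostic scoring for DNA-repair pathways in survival
cohorts** — maximally selected rank (maxstat) cutpoint screening, a
signed-weight global risk score (the *DRscore*), pathway sub-scores, and
fixed-cutoff validation on independent cohorts.

## The problem

Multiple myeloma tumors deregulate DNA-repair pathways (NHEJ, HR, FA,
NER, MMR, BER), and the expression of repair genes in malignant plasma
cells carries prognostic information. Given a MAS5-normalized microarray
expression matrix (probe sets × patients) and overall/event-free
survival follow-up, this package:

1. **Screens each gene** for a prognostic expression threshold. For a
   marker x, every admissible cut `x ≤ c` vs `x > c` (left-group
   fraction in [minprop, maxprop], default [0.1, 0.9]) is tested with
   the standardized log-rank statistic; the cut maximizing |z| is
   selected. Because a maximum is taken, the p-value must pay for the
   selection: the default `ls_approx` method evaluates the asymptotic
   Brownian-bridge null of the maximally selected rank statistic by
   exact numerical integration, and a permutation oracle is provided.
2. **Selects genes** with Benjamini–Hochberg FDR ≤ α (default 0.05) on
   *both* endpoints, with concordant hazard direction: **BAD** genes
   (dichotomized Cox HR > 1 on OS and EFS) and **GOOD** genes (HR < 1 on
   both).
3. **Builds the score**: each selected gene g gets a cutpoint c_g and a
   weight w_g = ln HR_g; a patient's score is

   ```
   DRscore = Σ_g s_g · w_g,   s_g = +1 if x_g > c_g, −1 if x_g ≤ c_g
   ```

   so a higher score always means worse prognosis. Pathway sub-scores
   apply the same rule to the genes of one repair pathway.
4. **Finds the score cutoff** S by the same maxstat search applied to
   the score against overall survival, and
5. **Validates** the frozen panel and cutoff on an independent cohort:
   high-risk iff score > S, with Kaplan–Meier curves, log-rank tests,
   uni-/multivariate Cox comparisons against clinical covariates, and
   chi-square association tables.

All survival statistics (Kaplan–Meier, log-rank, Cox with Efron or
Breslow tie handling, Pearson chi-square) are implemented in the package
and cross-checked against independent references in the test suite. A
synthetic-cohort generator with exact ground truth (threshold-effect
proportional hazards, coupled OS/EFS, independent censoring) makes every
stage testable without patient data, and the published 22-gene panel
(17 BAD, 5 GOOD) ships as a data fixture.

## Worked example

```sh
python examples/simulate_screen_score.py
```

```
simulated cohort: 84 probes x 300 patients; 41% OS events, 53% EFS events
dual-endpoint FDR<=0.05 screen selected 5 probes:
  probe_0008  BAD   OS: cut=  402.3 HR=2.75 FDR=1.7e-03
  ...
truth recovery: sensitivity 0.23, 0 false discoveries, cutpoint quantile error 0.059
score vs true log-hazard: Spearman rho = 0.61
score cutoff +1.09 splits the cohort 15.0% high / 85.0% low risk (OS log-rank p = 5.1e-23)
```

The screen recovers the strongest marginal threshold effects (with 22
simultaneous effect genes, each gene's *marginal* hazard ratio is much
smaller than its conditional one — see `docs/methods.md`), keeps false
discoveries at zero, localizes cutpoints to within ~0.06 quantile units,
and the resulting score stratifies survival sharply. Freezing the panel
and cutoff and applying them to an independent simulated cohort
(`examples/cutoff_transfer.py`) reproduces the stratification:

```
validation cohort: 19.3% high risk / 80.7% low risk at the frozen cutoff
  OS: median high-risk 8.0 mo, low-risk 97.9 mo, log-rank p = 3.4e-10
```

Other examples: `examples/published_panel.py` (the packaged 22-gene
panel: weight bound ±24.06, consistent with the published observed score
range −22.45 to +21.59), `examples/pathway_scores.py` (per-pathway
sub-scores and the MMSET/TP53 surrogate flags).

## Command line

```sh
drscore simulate --n-patients 206 --seed 1 --out sim/
drscore train --expression sim/expression.tsv --clinical sim/clinical.csv \
              --annotation sim/annotation.csv --out train/
drscore validate --expression new_cohort.tsv --clinical new_cohort.csv \
                 --panel train/panel.json --cutoff -7.62 --covariates iss,b2m
```

`train` writes a publication-style screen CSV, the panel JSON, per-patient
scores, the stratification report and a run manifest; `validate` applies
a frozen panel/cutoff and adds Cox-comparison and association tables.
`drscore --config run.yaml <subcommand>` reads per-subcommand option
defaults from a YAML file.

### File formats

* expression: TSV/CSV, first column `probe_id`, header row patient ids,
  non-negative signals, no missing values;
* clinical: CSV with `patient_id, os_time_months, os_event,
  efs_time_months, efs_event` plus free covariate columns;
* annotation: CSV `probe_id, gene_symbol, pathways` with `;`-separated
  pathway labels from {NHEJ, HR, FA, NER, MMR, BER};
* panel: JSON with `endpoint_used`, `weight_scale` and per-gene
  `{probe_id, cutpoint, weight, direction}`.

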