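"""End-to-end training run on a synthetic cohort with known truth.

Simulates a study-shaped cohort (84 probes, 22 genes with true threshold
effects, n=300), screens every probe against both survival endpoints,
builds the signed-weight score, finds the score-level cutpoint, and
reports how much of the generative truth was recovered.
"""

from scipy.stats import spearmanr

from drscore import (
    assign_risk_groups,
    build_panel,
    canonical_config,
    find_score_cutoff,
    score_cohort,
    screen_panel,
    simulate_cohort,
    truth_recovery_report,
)

cohort = simulate_cohort(canonical_config(n_patients=300, seed=1))
print(
    f"simulated cohort: {cohort.expression.shape[0]} probes x "
    f"{cohort.expression.shape[1]} patients; "
    f"{cohort.os.events.mean():.0%} OS events, {cohort.efs.events.mean():.0%} EFS events"
)

records = screen_panel(
    cohort.os, cohort.efs, cohort.expression.signals, cohort.expression.probe_ids
)
selected = [r for r in records if r.selected]
print(f"dual-endpoint FDR<=0.05 screen selected {len(selected)} probes:")
for r in selected:
    print(
        f"  {r.probe_id}  {r.direction:<5} OS: cut={r.os.cutpoint:7.1f} "
        f"HR={r.os.hazard_ratio:4.2f} FDR={r.os.fdr:.1e}"
    )

report = truth_recovery_report(records, cohort.truth, cohort.expression)
print(
    f"truth recovery: sensitivity {report['sensitivity']:.2f}, "
    f"{report['false_discoveries']} false discoveries, "
    f"cutpoint quantile error {report['cutpoint_quantile_error']:.3f}"
)

panel = build_panel(records)
scores = score_cohort(panel, cohort.expression)
rho = spearmanr(scores, cohort.truth.true_log_hazard).statistic
print(f"score vs true log-hazard: Spearman rho = {rho:.2f}")

cutoff = find_score_cutoff(scores, cohort.os)
strat = assign_risk_groups(scores, cutoff, cohort.os, cohort.efs)
lr = strat.by_endpoint["OS"].logrank
print(
    f"score cutoff {cutoff:+.2f} splits the cohort "
    f"{strat.proportions['high']:.1f}% high / {strat.proportions['low']:.1f}% low risk "
    f"(OS log-rank p = {lr.p_value:.1e})"
)
print()
print(
    "Screening with selection-adjusted p-values is conservative: only the\n"
    "strongest marginal effects survive the dual-endpoint FDR filter, but\n"
    "the resulting score still separates survival sharply."
)
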