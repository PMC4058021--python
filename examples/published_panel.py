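"""The packaged 22-gene DNA-repair panel and its signed-weight score.

Loads the published panel (probe sets, pathways, maxstat cutpoints and
dichotomized-Cox hazard ratios for OS and EFS), builds the log-weight
score, and scores two archetypal patients.
"""

from drscore import compute_score, load_published_panel, panel_from_records

records = load_published_panel()
panel = panel_from_records(records)

n_bad = sum(r.direction == "BAD" for r in records)
n_good = sum(r.direction == "GOOD" for r in records)
print(f"panel: {len(records)} genes ({n_bad} adverse, {n_good} protective)")
print(f"theoretical score range: ±{panel.weight_bound:.2f}")
print()
print(f"{'probe':<14}{'gene':<14}{'pathways':<10}{'dir':<6}{'cutpoint':>9}{'weight':>8}")
for g in panel.genes[:6]:
    print(
        f"{g.probe_id:<14}{g.gene_symbol:<14}{'/'.join(g.pathways):<10}"
        f"{g.direction:<6}{g.cutpoint:>9.0f}{g.weight:>8.3f}"
    )
print(f"... ({len(panel.genes) - 6} more genes)")

# a patient above every adverse cutpoint and below every protective one
worst = {
    g.probe_id: (g.cutpoint + 1 if g.direction == "BAD" else g.cutpoint - 1)
    for g in panel.genes
}
best = {
    g.probe_id: (g.cutpoint - 1 if g.direction == "BAD" else g.cutpoint + 1)
    for g in panel.genes
}
print()
print(f"worst-profile patient score: {compute_score(panel, worst):+.2f}")
print(f"best-profile patient score:  {compute_score(panel, best):+.2f}")
print()
print(
    "Each gene adds +w when expression exceeds its cutpoint and -w "
    "otherwise,\nwith w = ln(HR): higher scores mean worse prognosis."
)
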