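"""Pathway-specific sub-scores and expression surrogate flags.

Builds one risk score per DNA-repair pathway from the published panel
(genes on several pathways contribute to each of their pathways) and
shows the t(4;14)/del17p expression surrogates.
"""

from drscore import (
    compute_score,
    load_published_panel,
    panel_from_records,
    pathway_subpanel,
    surrogate_markers,
)

records = load_published_panel()
global_panel = panel_from_records(records)

# a patient with high double-strand-break repair expression only
patient = {}
for g in global_panel.genes:
    dsb = bool({"NHEJ", "HR"} & set(g.pathways))
    patient[g.probe_id] = g.cutpoint * (1.5 if dsb else 0.5)

print(f"{'pathway':<8}{'genes':>6}{'sub-score':>11}")
for pathway in ("NHEJ", "HR", "FA", "NER", "MMR", "BER"):
    panel = pathway_subpanel(records, pathway)
    score = compute_score(panel, patient)
    print(f"{pathway:<8}{len(panel.genes):>6}{score:>+11.2f}")
print(f"{'GLOBAL':<8}{len(global_panel.genes):>6}{compute_score(global_panel, patient):>+11.2f}")
print()
print(
    "Positive sub-scores flag pathways whose adverse genes this patient\n"
    "over-expresses — here the double-strand-break pathways (NHEJ/HR),\n"
    "candidates for pathway-targeted synthetic-lethality strategies."
)

# expression surrogates for two recurrent genetic lesions
flags = surrogate_markers(
    {"222777_s_at": 4200.0, "201746_at": 850.0},
    mmset_probe="222777_s_at",
    tp53_probe="201746_at",
    mmset_threshold=1000.0,  # spike-level MMSET/WHSC1 expression
    tp53_threshold=500.0,  # low TP53 suggesting 17p loss
)
print(f"t(4;14) surrogate (MMSET spike): {flags.t4_14}")
print(f"del17p surrogate (low TP53):     {flags.del17p}")
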