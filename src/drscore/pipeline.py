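"""End-to-end orchestration: simulate, train, score, validate.

``run_train`` screens an annotated probe panel on a training cohort,
builds the signed-weight score panel, scores every patient, searches the
score-level cutpoint and stratifies; ``run_validate`` applies a frozen
panel and cutoff to an independent cohort and compares the risk group
against supplied clinical covariates with univariate/multivariate Cox
fits and chi-square association tables.  Every run writes a manifest
(config, seed, outputs) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .screening import ScreenConfig, screen_panel
from .scoring import (
    PATHWAYS,
    ScorePanel,
    assign_risk_groups,
    build_panel,
    find_score_cutoff,
    pathway_subpanel,
    score_cohort,
)
from .survival import ValidationError, chi_square_association, cox_fit
from .synthetic import SimConfig, canonical_config, simulate_cohort

logger = logging.getLogger("drscore")

__all__ = ["PipelineConfig", "run_train", "run_validate", "run_simulate"]


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    clinical_path: str | None = None
    annotation_path: str | None = None
    output_dir: str = "drscore_out"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    weight_scale: str = "log_hr"
    endpoint: str = "OS"
    score_cutoff: float | str = "search"
    panel_path: str | None = None
    covariate_columns: tuple = ()
    seed: int = 0
    make_plots: bool = False
    sim: SimConfig | None = None


def _manifest(config, outputs, outdir):
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    cfg_json = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    path = Path(outdir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _load_cohort(config):
    matrix = io.read_expression_matrix(config.expression_path)
    clinical = io.read_clinical_table(config.clinical_path).aligned_to(matrix.patient_ids)
    return matrix, clinical


def _km_plot(strat, endpoint, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    es = strat.by_endpoint[endpoint]
    fig, ax = plt.subplots(figsize=(5, 4))
    for km, label, color in ((es.km_low, "low risk", "C0"), (es.km_high, "high risk", "C3")):
        if km is None or km.distinct_event_times.size == 0:
            continue
        t = np.concatenate([[0], np.repeat(km.distinct_event_times, 2)])
        s = np.concatenate([[1, 1], np.repeat(km.survival_probs, 2)[:-1]])
        ax.plot(t, s, label=label, color=color)
    p = es.logrank.p_value if es.logrank else float("nan")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_title(f"{endpoint}: log-rank p = {p:.1e}")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_train(config: PipelineConfig) -> dict:
    """Screen → panel → scores → score cutoff → stratification."""
    if config.annotation_path is None:
        raise ValidationError("training mode requires an annotation table")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, clinical = _load_cohort(config)
    annotation = io.read_annotation(config.annotation_path)
    probes = [p for p in matrix.probe_ids if p in annotation]
    if not probes:
        raise ValidationError("no annotated probes present in the expression matrix")
    os_data = clinical.survival("OS")
    efs_data = clinical.survival("EFS")
    logger.info("screening %d probes on %d patients (seed %d)", len(probes), len(os_data), config.seed)

    records = screen_panel(
        os_data, efs_data, matrix.rows(probes), probes, config.screen, annotation
    )
    panel = build_panel(records, config.endpoint, config.weight_scale)
    scores = score_cohort(panel, matrix)
    if config.score_cutoff == "search":
        cutoff = find_score_cutoff(scores, os_data, config.screen.minprop, config.screen.maxprop)
    else:
        cutoff = float(config.score_cutoff)
    strat = assign_risk_groups(scores, cutoff, os_data, efs_data)
    logger.info(
        "panel of %d genes; cutoff %.3f; %d high / %d low risk",
        len(panel.genes),
        cutoff,
        strat.n_high,
        strat.n_low,
    )

    outputs = {
        "screen_csv": outdir / "screen_results.csv",
        "panel_json": outdir / "panel.json",
        "scores_csv": outdir / "scores.csv",
        "stratification_csv": outdir / "stratification.csv",
    }
    io.write_screen_records(records, outputs["screen_csv"])
    io.write_panel_json(panel, outputs["panel_json"])
    io.write_scores_csv(matrix.patient_ids, scores, strat.labels, outputs["scores_csv"])
    io.write_stratification_report(strat, outputs["stratification_csv"])
    if config.make_plots:
        for ep in strat.by_endpoint:
            plot = outdir / f"km_{ep.lower()}.png"
            _km_plot(strat, ep, plot)
            outputs[f"km_plot_{ep.lower()}"] = plot
    manifest = _manifest(config, outputs, outdir)
    return {
        "records": records,
        "panel": panel,
        "scores": scores,
        "cutoff": cutoff,
        "stratification": strat,
        "outputs": outputs,
        "manifest": manifest,
    }


def _cox_table(os_data, design: pd.DataFrame, joint: bool) -> pd.DataFrame:
    """Univariate (or joint) Cox rows: one line per covariate."""
    rows = []
    if joint:
        fit = cox_fit(os_data, design.to_numpy(float), tuple(design.columns))
        for name, hr, p in zip(fit.covariate_names, fit.hazard_ratios, fit.wald_p_values):
            rows.append({"covariate": name, "hr": hr, "p": p, "model": "joint"})
    else:
        for name in design.columns:
            fit = cox_fit(os_data, design[[name]].to_numpy(float), (name,))
            rows.append(
                {"covariate": name, "hr": fit.hazard_ratios[0], "p": fit.wald_p_values[0], "model": "univariate"}
            )
    return pd.DataFrame(rows)


def run_validate(config: PipelineConfig) -> dict:
    """Apply a frozen panel + cutoff to an independent cohort."""
    if config.panel_path is None:
        raise ValidationError("validation mode requires a panel JSON")
    if config.score_cutoff == "search":
        raise ValidationError("validation mode requires an explicit, frozen score cutoff")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = io.read_panel_json(config.panel_path)
    matrix, clinical = _load_cohort(config)
    os_data = clinical.survival("OS")
    efs_data = clinical.survival("EFS")
    scores = score_cohort(panel, matrix)
    cutoff = float(config.score_cutoff)
    strat = assign_risk_groups(scores, cutoff, os_data, efs_data)

    outputs = {
        "scores_csv": outdir / "scores.csv",
        "stratification_csv": outdir / "stratification.csv",
    }
    io.write_scores_csv(matrix.patient_ids, scores, strat.labels, outputs["scores_csv"])
    io.write_stratification_report(strat, outputs["stratification_csv"])

    cox_tables = []
    chi_tables = []
    if config.covariate_columns:
        df = clinical.frame.copy()
        high = pd.Series([1.0 if l == "high" else 0.0 for l in strat.labels], index=df.index)
        for col in config.covariate_columns:
            if col not in df.columns:
                raise ValidationError(f"covariate column '{col}' absent from clinical table")
            if df[col].nunique() < 2:
                raise ValidationError(f"covariate column '{col}' is constant: not testable")
        base = pd.DataFrame({"risk_group": high})
        cox_tables.append(_cox_table(os_data, base, joint=False))
        # pairwise: score + one factor, then all factors jointly
        for col in config.covariate_columns:
            pair = pd.DataFrame({"risk_group": high, col: pd.to_numeric(df[col])})
            cox_tables.append(_cox_table(os_data, pair, joint=True))
        full = pd.DataFrame({"risk_group": high})
        for col in config.covariate_columns:
            full[col] = pd.to_numeric(df[col])
        cox_tables.append(_cox_table(os_data, full, joint=True))
        cox_df = pd.concat(cox_tables, ignore_index=True)
        outputs["cox_csv"] = outdir / "cox_comparison.csv"
        cox_df.to_csv(outputs["cox_csv"], index=False)
        # chi-square association of risk group with categorical covariates
        for col in config.covariate_columns:
            vals = df[col]
            if vals.nunique() <= 6:  # treat low-cardinality columns as categorical
                table = pd.crosstab(high, vals).to_numpy()
                res = chi_square_association(table)
                chi_tables.append({"covariate": col, "chi2": res.chi2, "df": res.df, "p": res.p_value})
        if chi_tables:
            outputs["association_csv"] = outdir / "association.csv"
            pd.DataFrame(chi_tables).to_csv(outputs["association_csv"], index=False)
    if config.make_plots:
        for ep in strat.by_endpoint:
            plot = outdir / f"km_{ep.lower()}.png"
            _km_plot(strat, ep, plot)
            outputs[f"km_plot_{ep.lower()}"] = plot
    manifest = _manifest(config, outputs, outdir)
    return {
        "panel": panel,
        "scores": scores,
        "stratification": strat,
        "cox_tables": cox_tables,
        "association": chi_tables,
        "outputs": outputs,
        "manifest": manifest,
    }


def run_simulate(config: PipelineConfig) -> dict:
    """Write a simulated cohort (expression TSV, clinical CSV, truth JSON)."""
    sim = config.sim if config.sim is not None else canonical_config(seed=config.seed)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(sim)
    outputs = {
        "expression_tsv": outdir / "expression.tsv",
        "clinical_csv": outdir / "clinical.csv",
        "truth_json": outdir / "truth.json",
        "annotation_csv": outdir / "annotation.csv",
    }
    io.write_expression_matrix(cohort.expression, outputs["expression_tsv"])
    io.write_clinical_table(cohort.clinical_table(), outputs["clinical_csv"])
    truth = {
        "effect_genes": [
            {
                "probe_id": cohort.expression.probe_ids[g.probe_index],
                "true_beta": g.true_beta,
                "true_cutpoint_quantile": g.true_cutpoint_quantile,
                "direction": g.direction,
                "cutpoint_signal": cohort.truth.cutpoint_signals[
                    cohort.expression.probe_ids[g.probe_index]
                ],
            }
            for g in cohort.truth.effect_genes
        ]
    }
    Path(outputs["truth_json"]).write_text(json.dumps(truth, indent=2))
    # simulated probes get an even spread of pathway labels so the whole
    # pipeline (including pathway sub-scores) runs on simulated data
    with open(outputs["annotation_csv"], "w") as fh:
        fh.write("probe_id,gene_symbol,pathways\n")
        for i, pid in enumerate(cohort.expression.probe_ids):
            fh.write(f"{pid},GENE{i:04d},{PATHWAYS[i % len(PATHWAYS)]}\n")
    manifest = _manifest(config, outputs, outdir)
    return {"cohort": cohort, "outputs": outputs, "manifest": manifest}
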