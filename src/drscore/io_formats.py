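"""Tabular readers/writers and the packaged 22-gene panel fixture.

Formats are deliberately plain: an expression matrix is a TSV/CSV with
probe-set ids in the first column and patient ids in the header row; the
clinical table is a CSV with ``patient_id, os_time_months, os_event,
efs_time_months, efs_event`` plus free covariate columns; pathway
annotation is ``probe_id, gene_symbol, pathways`` with ``;``-separated
pathway labels.  Readers validate eagerly and reject rather than coerce,
naming the offending row or column.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import PATHWAYS, PanelGene, ScorePanel
from .screening import EndpointScreen, GeneScreenRecord
from .survival import SurvivalData, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_annotation",
    "load_published_panel",
    "panel_from_records",
    "write_screen_records",
    "read_screen_records",
    "write_panel_json",
    "read_panel_json",
    "write_scores_csv",
    "write_stratification_report",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe-set × patient matrix of non-negative normalized signals."""

    probe_ids: tuple
    patient_ids: tuple
    signals: np.ndarray

    def __post_init__(self):
        sig = np.asarray(self.signals, dtype=float)
        if sig.shape != (len(self.probe_ids), len(self.patient_ids)):
            raise ValidationError("signal matrix shape does not match probe/patient ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dup = sorted({p for p in self.probe_ids if list(self.probe_ids).count(p) > 1})
            raise ValidationError(f"duplicate probe id(s): {dup}")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValidationError("duplicate patient ids")
        if np.any(~np.isfinite(sig)):
            raise ValidationError("missing or non-finite expression values are not allowed")
        if np.any(sig < 0):
            raise ValidationError("expression signals must be non-negative")
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))

    @property
    def shape(self):
        return self.signals.shape

    def rows(self, probe_ids) -> np.ndarray:
        """Signals for the requested probes, in the requested order."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise ValidationError(f"probe(s) absent from expression matrix: {missing}")
        return self.signals[[index[p] for p in probe_ids]]

    def row(self, probe_id) -> np.ndarray:
        return self.rows([probe_id])[0]

    def patient_vector(self, patient_id) -> dict:
        try:
            j = self.patient_ids.index(patient_id)
        except ValueError:
            raise ValidationError(f"unknown patient id {patient_id!r}") from None
        return dict(zip(self.probe_ids, self.signals[:, j]))


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient survival endpoints plus optional covariate columns."""

    frame: pd.DataFrame

    MANDATORY = ("patient_id", "os_time_months", "os_event", "efs_time_months", "efs_event")

    def __post_init__(self):
        df = self.frame
        for col in self.MANDATORY:
            if col not in df.columns:
                raise ValidationError(f"clinical table missing mandatory column '{col}'")
        if df["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id in clinical table")
        for col in ("os_time_months", "efs_time_months"):
            if not (pd.to_numeric(df[col], errors="coerce") > 0).all():
                bad = df.index[~(pd.to_numeric(df[col], errors="coerce") > 0)].tolist()
                raise ValidationError(f"non-positive or non-numeric {col} at row(s) {bad}")
        for col in ("os_event", "efs_event"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if not vals.isin([0, 1]).all():
                bad = df.index[~vals.isin([0, 1])].tolist()
                raise ValidationError(f"non-binary {col} at row(s) {bad}")

    def survival(self, endpoint: str) -> SurvivalData:
        df = self.frame
        if endpoint == "OS":
            return SurvivalData.from_arrays(
                df["os_time_months"].astype(float),
                df["os_event"].astype(int),
                "OS",
                df["patient_id"],
            )
        if endpoint == "EFS":
            return SurvivalData.from_arrays(
                df["efs_time_months"].astype(float),
                df["efs_event"].astype(int),
                "EFS",
                df["patient_id"],
            )
        raise ValidationError("endpoint must be 'OS' or 'EFS'")

    def aligned_to(self, patient_ids) -> "ClinicalTable":
        df = self.frame.set_index("patient_id")
        missing = [p for p in patient_ids if p not in df.index]
        if missing:
            raise ValidationError(f"patients missing from clinical table: {missing}")
        return ClinicalTable(df.loc[list(patient_ids)].reset_index())


def read_expression_matrix(path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a probe × patient matrix; first column probe ids, header patients."""
    path = Path(path)
    sep = dialect if dialect else ("\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no patient columns found")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(
        matrix.signals, index=list(matrix.probe_ids), columns=list(matrix.patient_ids)
    ).to_csv(path, sep=sep, index_label="probe_id")


def read_clinical_table(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path))


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_annotation(path) -> dict:
    """probe_id → (gene_symbol, pathway tuple) from an annotation CSV."""
    ann = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for col in ("probe_id", "gene_symbol", "pathways"):
            if col not in (reader.fieldnames or []):
                raise ValidationError(f"{path}: annotation missing column '{col}'")
        for i, row in enumerate(reader, start=2):
            pws = tuple(p.strip() for p in row["pathways"].split(";") if p.strip())
            bad = [p for p in pws if p not in PATHWAYS]
            if bad:
                raise ValidationError(f"{path} row {i}: unknown pathway label(s) {bad}")
            if not pws:
                raise ValidationError(f"{path} row {i}: empty pathway annotation")
            ann[row["probe_id"]] = (row["gene_symbol"], pws)
    return ann


# ---------------------------------------------------------------------------
# Packaged 22-gene panel fixture


def _fixture_path():
    return resources.files("drscore.data").joinpath("dna_repair_panel_22.csv")


def load_published_panel() -> list[GeneScreenRecord]:
    """The published 22-gene DNA-repair panel as screening records.

    Per-gene maxstat cutpoints, FDR and dichotomized-Cox hazard ratios
    for both endpoints, with pathway membership, exactly as printed.
    """
    records = []
    with _fixture_path().open(newline="") as fh:
        for row in csv.DictReader(fh):
            pathways = tuple(row["pathways"].split(";"))
            os_s = EndpointScreen(
                endpoint="OS",
                cutpoint=float(row["os_cutpoint"]),
                max_stat=float("nan"),
                raw_p=float("nan"),
                hazard_ratio=float(row["os_hr"]),
                fdr=float(row["os_fdr"]),
            )
            efs_s = EndpointScreen(
                endpoint="EFS",
                cutpoint=float(row["efs_cutpoint"]),
                max_stat=float("nan"),
                raw_p=float("nan"),
                hazard_ratio=float(row["efs_hr"]),
                fdr=float(row["efs_fdr"]),
            )
            records.append(
                GeneScreenRecord(
                    probe_id=row["probe_id"],
                    gene_symbol=row["gene_symbol"],
                    pathways=pathways,
                    os=os_s,
                    efs=efs_s,
                    direction=row["direction"],
                )
            )
    return records


def panel_from_records(records=None, endpoint="OS", weight_scale="log_hr") -> ScorePanel:
    """Score panel derived from screening records (default: the fixture)."""
    from .scoring import build_panel

    if records is None:
        records = load_published_panel()
    return build_panel(records, endpoint, weight_scale)


# ---------------------------------------------------------------------------
# Results writers / readers


_SCREEN_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "pathways",
    "direction",
    "os_cutpoint",
    "os_max_stat",
    "os_raw_p",
    "os_fdr",
    "os_hr",
    "efs_cutpoint",
    "efs_max_stat",
    "efs_raw_p",
    "efs_fdr",
    "efs_hr",
]


def write_screen_records(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "probe_id": r.probe_id,
                "gene_symbol": r.gene_symbol,
                "pathways": ";".join(r.pathways),
                "direction": r.direction,
                "os_cutpoint": r.os.cutpoint,
                "os_max_stat": r.os.max_stat,
                "os_raw_p": r.os.raw_p,
                "os_fdr": r.os.fdr,
                "os_hr": r.os.hazard_ratio,
                "efs_cutpoint": r.efs.cutpoint,
                "efs_max_stat": r.efs.max_stat,
                "efs_raw_p": r.efs.raw_p,
                "efs_fdr": r.efs.fdr,
                "efs_hr": r.efs.hazard_ratio,
            }
        )
    pd.DataFrame(rows, columns=_SCREEN_COLUMNS).to_csv(path, index=False)


def read_screen_records(path) -> list[GeneScreenRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        pathways = tuple(str(row["pathways"]).split(";")) if row["pathways"] else ()
        records.append(
            GeneScreenRecord(
                probe_id=str(row["probe_id"]),
                gene_symbol=str(row["gene_symbol"]),
                pathways=pathways,
                os=EndpointScreen(
                    "OS",
                    float(row["os_cutpoint"]),
                    float(row["os_max_stat"]),
                    float(row["os_raw_p"]),
                    float(row["os_hr"]),
                    float(row["os_fdr"]),
                ),
                efs=EndpointScreen(
                    "EFS",
                    float(row["efs_cutpoint"]),
                    float(row["efs_max_stat"]),
                    float(row["efs_raw_p"]),
                    float(row["efs_hr"]),
                    float(row["efs_fdr"]),
                ),
                direction=str(row["direction"]),
            )
        )
    return records


def write_panel_json(panel: ScorePanel, path) -> None:
    payload = {
        "endpoint_used": panel.endpoint_used,
        "weight_scale": panel.weight_scale,
        "pathway_label": panel.pathway_label,
        "genes": [
            {
                "probe_id": g.probe_id,
                "gene_symbol": g.gene_symbol,
                "pathways": list(g.pathways),
                "cutpoint": g.cutpoint,
                "weight": g.weight,
                "direction": g.direction,
            }
            for g in panel.genes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_panel_json(path) -> ScorePanel:
    payload = json.loads(Path(path).read_text())
    genes = tuple(
        PanelGene(
            g["probe_id"],
            g.get("gene_symbol", g["probe_id"]),
            tuple(g.get("pathways", ())),
            float(g["cutpoint"]),
            float(g["weight"]),
            g["direction"],
        )
        for g in payload["genes"]
    )
    return ScorePanel(
        genes,
        payload.get("endpoint_used", "OS"),
        payload.get("weight_scale", "log_hr"),
        payload.get("pathway_label", "GLOBAL"),
    )


def write_scores_csv(patient_ids, scores, labels, path) -> None:
    pd.DataFrame(
        {"patient_id": list(patient_ids), "drscore": list(scores), "risk_group": list(labels)}
    ).to_csv(path, index=False)


def write_stratification_report(strat, path) -> None:
    rows = []
    for endpoint, es in strat.by_endpoint.items():
        rows.append(
            {
                "endpoint": endpoint,
                "score_cutoff": strat.score_cutoff,
                "n_high": strat.n_high,
                "n_low": strat.n_low,
                "pct_high": strat.proportions["high"],
                "pct_low": strat.proportions["low"],
                "logrank_chi2": es.logrank.chi2 if es.logrank else math.nan,
                "logrank_p": es.logrank.p_value if es.logrank else math.nan,
                "median_high": es.median_high if es.median_high is not None else math.nan,
                "median_low": es.median_low if es.median_low is not None else math.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
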