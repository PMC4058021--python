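"""Signed-weight risk score (DRscore) construction and stratification.

Each selected gene g contributes s_g·w_g to a patient's score, where
s_g = +1 when the patient's expression exceeds the gene's maxstat
cutpoint c_g and −1 when it is below or equal, and w_g is the gene's
Cox weight.  With the default log-scale weights (w_g = ln HR_g) adverse
genes push the score up and protective genes pull it down, so a higher
score always means worse prognosis; a raw hazard-ratio weight scale is
retained for fidelity with score variants that sum the ratios
themselves.  The cohort-level cutoff S is found by the same maximally
selected rank search applied to the score, and frozen for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import maxstat as mx
from .survival import (
    KMCurve,
    LogRankResult,
    SurvivalData,
    ValidationError,
    km_estimate,
    logrank_test,
    median_survival,
)

__all__ = [
    "PanelGene",
    "ScorePanel",
    "RiskStratification",
    "EndpointStratification",
    "SurrogateFlags",
    "build_panel",
    "compute_score",
    "score_cohort",
    "find_score_cutoff",
    "assign_risk_groups",
    "pathway_subpanel",
    "surrogate_markers",
]

PATHWAYS = ("NHEJ", "HR", "FA", "NER", "MMR", "BER")


@dataclass(frozen=True)
class PanelGene:
    probe_id: str
    gene_symbol: str
    pathways: tuple
    cutpoint: float
    weight: float
    direction: str

    def __post_init__(self):
        if self.direction not in ("GOOD", "BAD"):
            raise ValidationError("panel genes must carry a GOOD or BAD direction")


@dataclass(frozen=True)
class ScorePanel:
    genes: tuple
    endpoint_used: str = "OS"
    weight_scale: str = "log_hr"
    pathway_label: str = "GLOBAL"

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("a score panel cannot be empty")
        ids = [g.probe_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate probe ids in panel")
        if self.weight_scale == "log_hr":
            for g in self.genes:
                if g.direction == "BAD" and g.weight <= 0:
                    raise ValidationError(f"{g.probe_id}: BAD gene must have positive log weight")
                if g.direction == "GOOD" and g.weight >= 0:
                    raise ValidationError(f"{g.probe_id}: GOOD gene must have negative log weight")

    @property
    def probe_ids(self) -> tuple:
        return tuple(g.probe_id for g in self.genes)

    @property
    def weight_bound(self) -> float:
        """Σ|w_g|: the score lies in [−bound, +bound] by construction."""
        return float(sum(abs(g.weight) for g in self.genes))


@dataclass(frozen=True)
class EndpointStratification:
    endpoint: str
    logrank: LogRankResult | None
    km_high: KMCurve | None
    km_low: KMCurve | None
    median_high: float | None
    median_low: float | None


@dataclass(frozen=True)
class RiskStratification:
    score_cutoff: float
    labels: tuple  # "high"/"low" per patient, high iff score > cutoff
    n_high: int
    n_low: int
    proportions: dict  # {"high": %, "low": %} to one decimal
    by_endpoint: dict  # endpoint label -> EndpointStratification


@dataclass(frozen=True)
class SurrogateFlags:
    t4_14: bool
    del17p: bool
    mmset_threshold: float
    tp53_threshold: float


def build_panel(
    screen_records,
    endpoint: str = "OS",
    weight_scale: str = "log_hr",
    pathway_label: str = "GLOBAL",
) -> ScorePanel:
    """Assemble a score panel from the selected screening records.

    Each selected record contributes its cutpoint from the requested
    endpoint and a weight of ln(HR) (default) or the raw HR.
    """
    if endpoint not in ("OS", "EFS"):
        raise ValidationError("endpoint must be 'OS' or 'EFS'")
    if weight_scale not in ("log_hr", "hr"):
        raise ValidationError("weight_scale must be 'log_hr' or 'hr'")
    selected = [r for r in screen_records if r.direction != "NONE"]
    if not selected:
        raise ValidationError("empty selection: no prognostic genes to build a panel from")
    genes = []
    for r in selected:
        ep = r.os if endpoint == "OS" else r.efs
        w = math.log(ep.hazard_ratio) if weight_scale == "log_hr" else ep.hazard_ratio
        genes.append(
            PanelGene(r.probe_id, r.gene_symbol, tuple(r.pathways), ep.cutpoint, w, r.direction)
        )
    return ScorePanel(tuple(genes), endpoint, weight_scale, pathway_label)


def compute_score(panel: ScorePanel, expression_vector: dict, missing: str = "error") -> float:
    """Per-patient score Σ_g s_g·w_g with s_g = +1 if x_g > c_g else −1.

    ``expression_vector`` maps probe_id → signal.  Missing probes raise
    by default; ``missing='drop'`` silently omits them (a documented
    deviation for panels applied to platforms lacking a probe).
    """
    score = 0.0
    for g in panel.genes:
        if g.probe_id not in expression_vector:
            if missing == "drop":
                continue
            raise ValidationError(f"expression value missing for panel probe {g.probe_id}")
        s = 1.0 if expression_vector[g.probe_id] > g.cutpoint else -1.0
        score += s * g.weight
    return score


def score_cohort(panel: ScorePanel, matrix) -> np.ndarray:
    """Score every patient column of an expression matrix, in order."""
    sub = matrix.rows(panel.probe_ids)  # raises listing missing probes
    signals = sub  # probes × patients, aligned with panel order
    cuts = np.array([g.cutpoint for g in panel.genes])[:, None]
    weights = np.array([g.weight for g in panel.genes])[:, None]
    signs = np.where(signals > cuts, 1.0, -1.0)
    return (signs * weights).sum(axis=0)


def find_score_cutoff(
    scores,
    os: SurvivalData,
    minprop: float = mx.DEFAULT_MINPROP,
    maxprop: float = mx.DEFAULT_MAXPROP,
) -> float:
    """Maximally selected cutpoint of the score against overall survival."""
    scan = mx.cutpoint_scan(os, np.asarray(scores, dtype=float), minprop, maxprop)
    return mx.maxstat_select(scan).best_cutpoint


def _stratify_endpoint(survival: SurvivalData, high: np.ndarray) -> EndpointStratification:
    km_h = km_estimate(survival.subset(high)) if high.any() else None
    km_l = km_estimate(survival.subset(~high)) if (~high).any() else None
    if high.any() and (~high).any() and survival.events.sum() > 0:
        lr = logrank_test(survival, high.astype(int))
    else:
        lr = None  # one group empty: log-rank undefined
    return EndpointStratification(
        endpoint=survival.endpoint_label,
        logrank=lr,
        km_high=km_h,
        km_low=km_l,
        median_high=median_survival(km_h) if km_h is not None else None,
        median_low=median_survival(km_l) if km_l is not None else None,
    )


def assign_risk_groups(
    scores,
    cutoff: float,
    os: SurvivalData,
    efs: SurvivalData | None = None,
) -> RiskStratification:
    """High-risk iff score > cutoff; KM, medians and log-rank per endpoint."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(cutoff):
        raise ValidationError("score cutoff must be finite")
    high = scores > cutoff
    n = scores.size
    by_endpoint = {"OS": _stratify_endpoint(os, high)}
    if efs is not None:
        by_endpoint["EFS"] = _stratify_endpoint(efs, high)
    return RiskStratification(
        score_cutoff=float(cutoff),
        labels=tuple("high" if h else "low" for h in high),
        n_high=int(high.sum()),
        n_low=int(n - high.sum()),
        proportions={
            "high": round(100.0 * high.sum() / n, 1),
            "low": round(100.0 * (n - high.sum()) / n, 1),
        },
        by_endpoint=by_endpoint,
    )


def pathway_subpanel(
    screen_records,
    pathway: str,
    endpoint: str = "OS",
    weight_scale: str = "log_hr",
) -> ScorePanel:
    """Panel restricted to selected genes annotated to one repair pathway.

    Genes annotated to several pathways appear in every sub-panel they
    belong to (and once in the global panel).
    """
    if pathway not in PATHWAYS:
        raise ValidationError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    members = [r for r in screen_records if r.direction != "NONE" and pathway in r.pathways]
    if not members:
        raise ValidationError(f"no selected genes annotated to pathway {pathway}")
    return build_panel(members, endpoint, weight_scale, pathway_label=pathway)


def surrogate_markers(
    expression_vector: dict,
    mmset_probe: str,
    tp53_probe: str,
    mmset_threshold: float | None = None,
    tp53_threshold: float | None = None,
) -> SurrogateFlags:
    """Expression surrogates for t(4;14) and del17p.

    t(4;14) is flagged by an MMSET/WHSC1 spike (signal strictly above
    the configured threshold), del17p by low TP53 (signal strictly below
    its threshold).  Thresholds are platform- and cohort-specific and
    therefore mandatory configuration.
    """
    if mmset_threshold is None or tp53_threshold is None:
        raise ValidationError(
            "surrogate thresholds are required configuration: supply both "
            "mmset_threshold and tp53_threshold (no defaults exist)"
        )
    for probe in (mmset_probe, tp53_probe):
        if probe not in expression_vector:
            raise ValidationError(f"surrogate probe {probe} absent from expression vector")
    return SurrogateFlags(
        t4_14=bool(expression_vector[mmset_probe] > mmset_threshold),
        del17p=bool(expression_vector[tp53_probe] < tp53_threshold),
        mmset_threshold=float(mmset_threshold),
        tp53_threshold=float(tp53_threshold),
    )
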