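"""Per-gene prognostic screening against OS and EFS.

Each probe set is scanned for its maximally selected cutpoint on both
endpoints; a dichotomized univariate Cox fit at the selected cutpoint
yields the hazard ratio of high (x > c*) vs low expressors.  p-values
are Benjamini–Hochberg adjusted within endpoint across the screened
panel, and a probe is called prognostic only when its FDR clears the
threshold on *both* endpoints with (by default) a concordant hazard
direction — BAD when high expression is adverse on both, GOOD when
protective on both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import maxstat as mx
from .survival import SurvivalData, ValidationError, cox_fit

__all__ = [
    "EndpointScreen",
    "GeneScreenRecord",
    "ScreenConfig",
    "bh_adjust",
    "screen_gene",
    "screen_panel",
    "classify_direction",
]

GOOD, BAD, NONE = "GOOD", "BAD", "NONE"


@dataclass(frozen=True)
class EndpointScreen:
    """Per-endpoint screening result: the published gene-table triplet."""

    endpoint: str
    cutpoint: float
    max_stat: float
    raw_p: float
    hazard_ratio: float
    fdr: float = float("nan")
    n_candidates: int = 0


@dataclass(frozen=True)
class GeneScreenRecord:
    probe_id: str
    gene_symbol: str
    pathways: tuple
    os: EndpointScreen
    efs: EndpointScreen
    direction: str = NONE

    @property
    def selected(self) -> bool:
        return self.direction != NONE


@dataclass(frozen=True)
class ScreenConfig:
    """Screening policy knobs.

    alpha is the per-endpoint FDR threshold; p_method selects the
    maxstat p-value (selection-adjusted ``ls_approx`` or the unadjusted
    ``naive_logrank``); minprop/maxprop bound the admissible left-group
    fraction of candidate cutpoints.
    """

    alpha: float = 0.05
    minprop: float = mx.DEFAULT_MINPROP
    maxprop: float = mx.DEFAULT_MAXPROP
    p_method: str = "ls_approx"
    ties_method: str = "efron"
    require_both_endpoints: bool = True
    require_consistent_direction: bool = True

    def __post_init__(self):
        if not 0 <= self.alpha < 1:
            raise ValidationError("alpha must lie in [0, 1)")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    out = np.empty(m)
    out[order] = adj
    return out


def _screen_endpoint(survival: SurvivalData, x, config: ScreenConfig) -> EndpointScreen:
    scan = mx.cutpoint_scan(survival, x, config.minprop, config.maxprop)
    best = mx.maxstat_select(scan)
    p = mx.maxstat_pvalue(
        best.max_stat, scan.left_fractions, config.p_method, score_max_stat=scan.score_max_stat
    )
    high = (np.asarray(x, dtype=float) > best.best_cutpoint).astype(float)
    fit = cox_fit(survival, high[:, None], ("high_expression",), config.ties_method)
    return EndpointScreen(
        endpoint=survival.endpoint_label,
        cutpoint=best.best_cutpoint,
        max_stat=best.max_stat,
        raw_p=p,
        hazard_ratio=float(fit.hazard_ratios[0]),
        n_candidates=best.n_candidates,
    )


def screen_gene(
    os: SurvivalData,
    efs: SurvivalData,
    expression_row,
    config: ScreenConfig = ScreenConfig(),
    probe_id: str = "",
    gene_symbol: str = "",
    pathways: tuple = (),
) -> GeneScreenRecord:
    """Maxstat screen of one probe against both endpoints (FDR unset)."""
    x = np.asarray(expression_row, dtype=float)
    if x.shape[0] != len(os) or x.shape[0] != len(efs):
        raise ValidationError("expression row does not align with the endpoints")
    return GeneScreenRecord(
        probe_id=probe_id,
        gene_symbol=gene_symbol,
        pathways=tuple(pathways),
        os=_screen_endpoint(os, x, config),
        efs=_screen_endpoint(efs, x, config),
    )


def classify_direction(
    hr_os: float,
    hr_efs: float,
    selected_os: bool,
    selected_efs: bool,
    config: ScreenConfig = ScreenConfig(),
) -> str:
    """GOOD/BAD/NONE call from per-endpoint hazard ratios and selection."""
    if hr_os <= 0 or hr_efs <= 0:
        raise ValidationError("hazard ratios must be positive")
    if config.require_both_endpoints:
        if not (selected_os and selected_efs):
            return NONE
    elif not (selected_os or selected_efs):
        return NONE
    if hr_os > 1 and hr_efs > 1:
        return BAD
    if hr_os < 1 and hr_efs < 1:
        return GOOD
    if config.require_consistent_direction:
        return NONE
    # relaxed mode: let the OS direction decide on discordance
    return BAD if hr_os > 1 else GOOD


def screen_panel(
    os: SurvivalData,
    efs: SurvivalData,
    expression,
    probe_ids,
    config: ScreenConfig = ScreenConfig(),
    annotation: dict | None = None,
) -> list[GeneScreenRecord]:
    """Screen a probe panel, BH-adjust within endpoint, call directions.

    ``expression`` is a probe × patient array aligned with ``probe_ids``;
    ``annotation`` optionally maps probe_id → (gene_symbol, pathways).
    Records are returned sorted by OS FDR ascending.
    """
    probe_ids = list(probe_ids)
    if len(probe_ids) < 2:
        raise ValidationError("BH correction needs at least two probes")
    expr = np.asarray(expression, dtype=float)
    if expr.shape[0] != len(probe_ids):
        raise ValidationError("expression rows do not match probe_ids")
    annotation = annotation or {}
    records = []
    for i, pid in enumerate(probe_ids):
        sym, pws = annotation.get(pid, (pid, ()))
        records.append(
            screen_gene(os, efs, expr[i], config, probe_id=pid, gene_symbol=sym, pathways=pws)
        )
    fdr_os = bh_adjust([r.os.raw_p for r in records])
    fdr_efs = bh_adjust([r.efs.raw_p for r in records])
    out = []
    for r, qo, qe in zip(records, fdr_os, fdr_efs):
        os_s = replace(r.os, fdr=float(qo))
        efs_s = replace(r.efs, fdr=float(qe))
        direction = classify_direction(
            os_s.hazard_ratio,
            efs_s.hazard_ratio,
            os_s.fdr <= config.alpha,
            efs_s.fdr <= config.alpha,
            config,
        )
        out.append(replace(r, os=os_s, efs=efs_s, direction=direction))
    out.sort(key=lambda r: (r.os.fdr, r.probe_id))
    return out
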