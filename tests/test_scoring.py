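"""Score construction, stratification, pathway sub-scores, surrogates."""

import math

import numpy as np
import pytest

from drscore import (
    PanelGene,
    ScorePanel,
    SurvivalData,
    assign_risk_groups,
    build_panel,
    compute_score,
    find_score_cutoff,
    load_published_panel,
    pathway_subpanel,
    score_cohort,
    surrogate_markers,
)
from drscore.io_formats import ExpressionMatrix
from drscore.maxstat import cutpoint_scan, maxstat_select
from drscore.survival import ValidationError, logrank_test
from tests.conftest import random_cohort


@pytest.fixture(scope="module")
def fixture_records():
    return load_published_panel()


@pytest.fixture(scope="module")
def os_panel(fixture_records):
    return build_panel(fixture_records, endpoint="OS", weight_scale="log_hr")


def extreme_patient(panel, high_for):
    """Expression vector above/below each gene's cutpoint by direction."""
    vec = {}
    for g in panel.genes:
        above = g.direction in high_for
        vec[g.probe_id] = g.cutpoint * (2.0 if above else 0.5) + (1.0 if above else 0.0)
    return vec


class TestBuildPanel:
    def test_published_panel_weights(self, os_panel):
        assert len(os_panel.genes) == 22
        whsc1 = next(g for g in os_panel.genes if g.probe_id == "222777_s_at")
        assert whsc1.cutpoint == 1506
        assert whsc1.weight == pytest.approx(math.log(3.7))

    def test_protective_gene_gets_negative_log_weight(self, fixture_records):
        panel = build_panel(fixture_records)
        ercc1 = next(g for g in panel.genes if g.gene_symbol == "ERCC1")
        assert ercc1.weight == pytest.approx(math.log(0.4))
        assert ercc1.weight < 0

    def test_raw_hazard_ratio_scale_passthrough(self, fixture_records):
        panel = build_panel(fixture_records, weight_scale="hr")
        ercc1 = next(g for g in panel.genes if g.gene_symbol == "ERCC1")
        assert ercc1.weight == pytest.approx(0.4)

    def test_empty_selection_rejected(self, fixture_records):
        from dataclasses import replace

        nones = [replace(r, direction="NONE") for r in fixture_records]
        with pytest.raises(ValidationError, match="empty selection"):
            build_panel(nones)


class TestComputeScore:
    def test_worst_case_patient_hits_upper_bound(self, os_panel):
        vec = extreme_patient(os_panel, high_for={"BAD"})
        assert compute_score(os_panel, vec) == pytest.approx(os_panel.weight_bound)
        assert os_panel.weight_bound == pytest.approx(24.055, abs=0.01)

    def test_mirror_patient_is_global_sign_flip(self, os_panel):
        vec = extreme_patient(os_panel, high_for={"GOOD"})
        assert compute_score(os_panel, vec) == pytest.approx(-os_panel.weight_bound)

    def test_expression_at_cutpoint_counts_as_low(self):
        gene = PanelGene("p1", "G1", ("HR",), 100.0, 0.8, "BAD")
        panel = ScorePanel((gene,))
        assert compute_score(panel, {"p1": 100.0}) == pytest.approx(-0.8)
        assert compute_score(panel, {"p1": 100.0 + 1e-9}) == pytest.approx(0.8)

    def test_additive_over_disjoint_subpanels(self, os_panel, rng):
        vec = {g.probe_id: g.cutpoint * rng.uniform(0.5, 2.0) for g in os_panel.genes}
        half = len(os_panel.genes) // 2
        a = ScorePanel(os_panel.genes[:half])
        b = ScorePanel(os_panel.genes[half:])
        assert compute_score(os_panel, vec) == pytest.approx(
            compute_score(a, vec) + compute_score(b, vec)
        )

    def test_panel_order_irrelevant(self, os_panel, rng):
        vec = {g.probe_id: g.cutpoint * rng.uniform(0.5, 2.0) for g in os_panel.genes}
        shuffled = ScorePanel(tuple(rng.permutation(np.array(os_panel.genes, dtype=object))))
        assert compute_score(shuffled, vec) == pytest.approx(compute_score(os_panel, vec))

    def test_raising_adverse_gene_adds_twice_its_weight(self, os_panel, rng):
        vec = {g.probe_id: g.cutpoint * 0.5 for g in os_panel.genes}
        base = compute_score(os_panel, vec)
        bad = next(g for g in os_panel.genes if g.direction == "BAD")
        vec[bad.probe_id] = bad.cutpoint * 2
        assert compute_score(os_panel, vec) == pytest.approx(base + 2 * bad.weight)
        assert bad.weight > 0

    def test_missing_probe_rejected_or_dropped(self, os_panel):
        vec = extreme_patient(os_panel, high_for={"BAD"})
        removed = os_panel.genes[0].probe_id
        del vec[removed]
        with pytest.raises(ValidationError, match=removed):
            compute_score(os_panel, vec)
        dropped = compute_score(os_panel, vec, missing="drop")
        assert dropped == pytest.approx(
            os_panel.weight_bound - abs(os_panel.genes[0].weight)
        )

    def test_score_bounded_by_total_weight(self, os_panel, rng):
        for _ in range(20):
            vec = {g.probe_id: g.cutpoint * rng.uniform(0.2, 5.0) for g in os_panel.genes}
            assert abs(compute_score(os_panel, vec)) <= os_panel.weight_bound + 1e-12

    def test_bound_brackets_published_observed_range(self, os_panel):
        assert os_panel.weight_bound >= 21.59
        assert -os_panel.weight_bound <= -22.45


class TestScoreCohort:
    def make_matrix(self, panel, n, rng):
        signals = np.array(
            [g.cutpoint * rng.uniform(0.4, 2.5, n) for g in panel.genes]
        )
        return ExpressionMatrix(
            tuple(g.probe_id for g in panel.genes),
            tuple(f"P{i}" for i in range(n)),
            signals,
        )

    def test_matches_per_patient_scores(self, os_panel, rng):
        mat = self.make_matrix(os_panel, 10, rng)
        scores = score_cohort(os_panel, mat)
        for j, pid in enumerate(mat.patient_ids):
            assert scores[j] == pytest.approx(
                compute_score(os_panel, mat.patient_vector(pid))
            )

    def test_duplicate_patients_get_equal_scores(self, os_panel, rng):
        mat = self.make_matrix(os_panel, 4, rng)
        dup = ExpressionMatrix(
            mat.probe_ids, ("a", "b"), np.column_stack([mat.signals[:, 0]] * 2)
        )
        s = score_cohort(os_panel, dup)
        assert s[0] == s[1]

    def test_column_permutation_permutes_scores(self, os_panel, rng):
        mat = self.make_matrix(os_panel, 8, rng)
        perm = rng.permutation(8)
        mat2 = ExpressionMatrix(
            mat.probe_ids, tuple(mat.patient_ids[i] for i in perm), mat.signals[:, perm]
        )
        np.testing.assert_allclose(score_cohort(os_panel, mat2), score_cohort(os_panel, mat)[perm])

    def test_missing_panel_probe_reported(self, os_panel, rng):
        mat = self.make_matrix(os_panel, 5, rng)
        short = ExpressionMatrix(mat.probe_ids[:-1], mat.patient_ids, mat.signals[:-1])
        with pytest.raises(ValidationError, match=os_panel.genes[-1].probe_id):
            score_cohort(os_panel, short)


class TestGlobalVersusPathwayDecomposition:
    def test_global_score_is_pathway_sum_minus_overlap(self, fixture_records, rng):
        # genes on k pathways are counted k times across sub-scores but
        # once globally, so the sum of sub-scores exceeds the global score
        # by exactly the multi-membership contributions
        global_panel = build_panel(fixture_records)
        vec = {g.probe_id: g.cutpoint * rng.uniform(0.4, 2.5) for g in global_panel.genes}
        total = 0.0
        for pw in ("NHEJ", "HR", "FA", "NER", "MMR", "BER"):
            total += compute_score(pathway_subpanel(fixture_records, pw), vec)
        overlap = 0.0
        for g in global_panel.genes:
            rec = next(r for r in fixture_records if r.probe_id == g.probe_id)
            extra = len(rec.pathways) - 1
            s = 1.0 if vec[g.probe_id] > g.cutpoint else -1.0
            overlap += extra * s * g.weight
        assert compute_score(global_panel, vec) == pytest.approx(total - overlap)


class TestFindScoreCutoff:
    def test_equals_brute_force_scan(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 50))
            s = random_cohort(rng, n)
            if s.events.sum() < 2:
                continue
            scores = np.round(rng.normal(size=n) * 5, 1)
            try:
                got = find_score_cutoff(scores, s)
            except ValidationError:
                continue
            best, best_z = None, -1.0
            for c in np.unique(scores):
                left = scores <= c
                if not 0.1 <= left.mean() <= 0.9 or left.all():
                    continue
                z = abs(logrank_test(s, left.astype(int)).z_statistic)
                if z > best_z + 1e-12:
                    best, best_z = c, z
            assert got == pytest.approx(best)

    def test_separated_clusters_split_between_them(self):
        # low-score cluster lives long, high-score cluster dies early
        scores = np.r_[np.full(10, -8.0), np.full(10, 4.0)]
        times = np.r_[np.linspace(50, 90, 10), np.linspace(2, 12, 10)]
        s = SurvivalData.from_arrays(times, np.ones(20, int))
        cut = find_score_cutoff(scores, s)
        assert cut == pytest.approx(-8.0)  # boundary value: ≤ -8 vs > -8

    def test_constant_scores_rejected(self, rng):
        s = random_cohort(rng, 30)
        with pytest.raises(ValidationError):
            find_score_cutoff(np.full(30, 1.5), s)


class TestAssignRiskGroups:
    def test_boundary_patients_are_low_risk(self, rng):
        scores = np.array([-10.0, -8.0, -7.62, -5.0])
        s = random_cohort(rng, 4)
        strat = assign_risk_groups(scores, -7.62, s)
        assert strat.labels == ("low", "low", "low", "high")
        assert strat.n_high == 1 and strat.n_low == 3

    def test_cutoff_below_minimum_puts_everyone_high(self, rng):
        s = random_cohort(rng, 10)
        strat = assign_risk_groups(rng.normal(size=10), -1e9, s)
        assert strat.n_high == 10
        assert strat.by_endpoint["OS"].logrank is None  # undefined, not crashed

    def test_proportions_printed_to_one_decimal(self, rng):
        s = random_cohort(rng, 206)
        scores = np.r_[np.ones(51), -np.ones(155)]
        strat = assign_risk_groups(scores, 0.0, s)
        assert strat.proportions == {"high": 24.8, "low": 75.2}


class TestPathwaySubpanels:
    def test_published_pathway_memberships(self, fixture_records):
        nhej = pathway_subpanel(fixture_records, "NHEJ")
        assert {g.gene_symbol for g in nhej.genes} == {
            "WHSC1/MMSET",
            "RIF1",
            "XRCC5/KU80",
            "PNKP",
            "POLL",
        }
        hr = pathway_subpanel(fixture_records, "HR")
        assert len(hr.genes) == 6
        assert "EXO1" in {g.gene_symbol for g in hr.genes}
        fa = pathway_subpanel(fixture_records, "FA")
        assert len(fa.genes) == 3
        assert all(g.direction == "BAD" for g in fa.genes)

    def test_multi_pathway_gene_in_every_panel(self, fixture_records):
        for pw in ("HR", "MMR"):
            assert "EXO1" in {g.gene_symbol for g in pathway_subpanel(fixture_records, pw).genes}

    def test_single_gene_pathway_allowed(self, fixture_records):
        ber = pathway_subpanel(fixture_records, "BER")
        assert [g.gene_symbol for g in ber.genes] == ["LIG3"]

    def test_unknown_pathway_rejected(self, fixture_records):
        with pytest.raises(ValidationError, match="unknown pathway"):
            pathway_subpanel(fixture_records, "TLS")


class TestSurrogateMarkers:
    def test_thresholds_are_mandatory(self):
        with pytest.raises(ValidationError, match="threshold"):
            surrogate_markers({"m": 1.0, "p": 1.0}, "m", "p")

    def test_spike_expression_flags_translocation(self):
        flags = surrogate_markers(
            {"m": 5000.0, "p": 900.0}, "m", "p", mmset_threshold=500.0, tp53_threshold=300.0
        )
        assert flags.t4_14 is True
        assert flags.del17p is False

    def test_tp53_at_threshold_is_not_deleted(self):
        flags = surrogate_markers(
            {"m": 10.0, "p": 300.0}, "m", "p", mmset_threshold=500.0, tp53_threshold=300.0
        )
        assert flags.del17p is False

    def test_unrelated_probes_ignored(self, rng):
        base = {"m": 600.0, "p": 100.0}
        a = surrogate_markers(base, "m", "p", mmset_threshold=500.0, tp53_threshold=300.0)
        noisy = dict(base, other=float(rng.uniform(0, 1e5)))
        b = surrogate_markers(noisy, "m", "p", mmset_threshold=500.0, tp53_threshold=300.0)
        assert (a.t4_14, a.del17p) == (b.t4_14, b.del17p)
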