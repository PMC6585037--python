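import numpy as np
import pytest

from coupledesign.phenotype_sim import pfba
from coupledesign.screen_analyze import (
    FilterCriteria,
    PathwayMatrix,
    bpcy,
    build_report,
    carbon_count,
    carbon_yield,
    filter_strategies,
    knockout_frequency,
    pathway_delta,
    pathway_distribution,
    production_robustness,
)


@pytest.fixture
def criteria():
    return FilterCriteria(product_id="R_p")


class TestFilterStrategies:
    def test_toy_b_known_outcomes(self, toy_b, criteria):
        strategies = [set(), {"R_2"}, {"R_s"}]
        kept, rejected = filter_strategies(toy_b, strategies, criteria)
        assert kept == [frozenset({"R_2"})]
        reasons = dict(rejected)
        assert reasons[frozenset()] == "coupling"
        assert reasons[frozenset({"R_s"})] == "growth"

    def test_environment_failure_reported_first(self, toy_b, criteria):
        from coupledesign.model_core import Environment

        crit = FilterCriteria(product_id="R_p", env=Environment({"R_bio": (20.0, 30.0)}))
        with pytest.raises(RuntimeError, match="wild-type"):
            filter_strategies(toy_b, [{"R_2"}], crit)

    def test_infeasible_mutant_rejected_as_environment(self, toy_b_maint, criteria):
        # knocking out the only maintenance route while R_m demands flux
        kept, rejected = filter_strategies(toy_b_maint, [{"R_1", "R_2"}], criteria)
        assert kept == []
        assert rejected[0][1] == "environment"

    def test_empty_input(self, toy_b, criteria):
        assert filter_strategies(toy_b, [], criteria) == ([], [])

    def test_filtering_is_idempotent(self, toy_b, criteria):
        kept, _ = filter_strategies(toy_b, [set(), {"R_2"}, {"R_s"}], criteria)
        kept2, rejected2 = filter_strategies(toy_b, kept, criteria)
        assert kept2 == kept
        assert rejected2 == []

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(product_id="R_p", min_growth_fraction_of_wt=0.0)


class TestProductionRobustness:
    def test_high_fraction(self, toy_b):
        assert production_robustness(toy_b, {"R_2"}, 0.9, "R_p") == pytest.approx(9.0)

    def test_low_fraction(self, toy_b):
        assert production_robustness(toy_b, {"R_2"}, 0.01, "R_p") == pytest.approx(0.1)

    def test_wild_type_not_robust(self, toy_b):
        assert production_robustness(toy_b, set(), 0.9, "R_p") == pytest.approx(0.0)

    def test_monotone_in_fraction(self, toy_b):
        values = [production_robustness(toy_b, {"R_2"}, x, "R_p")
                  for x in (0.01, 0.25, 0.5, 0.9)]
        assert values == sorted(values)
        assert all(v >= 0 for v in values)


class TestBPCY:
    def test_formula(self):
        assert bpcy(10.0, 10.0, 10.0) == pytest.approx(10.0)

    def test_paper_uptake_value(self):
        assert bpcy(0.2, 0.5, 1.15) == pytest.approx(0.2 * 0.5 / 1.15)
        assert bpcy(0.2, 0.5, 1.15) == pytest.approx(0.08696, abs=5e-6)

    def test_zero_growth(self):
        assert bpcy(0.0, 5.0, 1.0) == 0.0

    def test_zero_uptake_rejected(self):
        with pytest.raises(ValueError):
            bpcy(1.0, 1.0, 0.0)


class TestCarbonYield:
    def test_succinate_from_glucose(self):
        assert carbon_yield(1.0, 1.15, 4, 6) == pytest.approx(4.0 / (1.15 * 6.0))
        assert carbon_yield(1.0, 1.15, 4, 6) == pytest.approx(0.5797, abs=5e-5)

    def test_zero_product(self):
        assert carbon_yield(0.0, 1.0, 4, 6) == 0.0

    def test_carbon_balance_case(self):
        assert carbon_yield(1.5, 1.0, 4, 6) == pytest.approx(1.0)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            carbon_yield(1.0, 1.0, 0, 6)


def test_carbon_count_parsing():
    assert carbon_count("C6H12O6") == 6
    assert carbon_count("CO2") == 1
    assert carbon_count("H2O") == 0
    assert carbon_count("CaCl2") == 0


@pytest.fixture
def toy_b_pathways(toy_b):
    p = np.zeros((2, toy_b.n_reactions), dtype=int)
    for rid in ("R_s", "R_1"):
        p[0, toy_b.index(rid)] = 1
    for rid in ("R_2", "R_3"):
        p[1, toy_b.index(rid)] = 1
    return PathwayMatrix(p=p, pathways=["P1", "P2"], reactions=list(toy_b.reaction_ids))


class TestPathwayDistribution:
    def test_counting(self, toy_b, toy_b_pathways):
        v = {"R_s": 1.0, "R_1": 2.0, "R_3": 0.5}
        d = pathway_distribution(v, toy_b_pathways)
        np.testing.assert_allclose(d, [1.0, 0.5])

    def test_all_zero(self, toy_b_pathways):
        np.testing.assert_allclose(pathway_distribution({}, toy_b_pathways), [0.0, 0.0])

    def test_all_active(self, toy_b, toy_b_pathways):
        v = {r: 1.0 for r in toy_b.reaction_ids}
        np.testing.assert_allclose(pathway_distribution(v, toy_b_pathways), [1.0, 1.0])

    def test_entries_in_unit_interval(self, toy_b, toy_b_pathways):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = {r: rng.normal() for r in toy_b.reaction_ids}
            d = pathway_distribution(v, toy_b_pathways)
            assert np.all(d >= 0) and np.all(d <= 1)

    def test_empty_pathway_row_dropped(self, toy_b):
        p = np.zeros((2, toy_b.n_reactions), dtype=int)
        p[0, toy_b.index("R_s")] = 1
        pm = PathwayMatrix(p=p, pathways=["P1", "EMPTY"],
                           reactions=list(toy_b.reaction_ids))
        assert pm.pathways == ["P1"]
        assert pm.p.shape[0] == 1


class TestPathwayDelta:
    def test_self_difference_is_zero(self, toy_b, toy_b_pathways):
        wt = pfba(toy_b)
        np.testing.assert_allclose(
            pathway_delta([wt], wt, toy_b_pathways), [0.0, 0.0], atol=1e-12
        )

    def test_toy_b_mutant_p2_delta_zero(self, toy_b, toy_b_pathways):
        from coupledesign.model_core import apply_knockouts

        wt = pfba(toy_b)
        mut = pfba(apply_knockouts(toy_b, {"R_2"}))
        delta = pathway_delta([mut], wt, toy_b_pathways)
        # WT uses R_2 (of P2), mutant uses R_3 (of P2): both d(P2) = 0.5
        assert delta[1] == pytest.approx(0.0, abs=1e-9)
        # mutant activates R_1 so P1 rises from 0.5 to 1.0
        assert delta[0] == pytest.approx(0.5)

    def test_delta_in_minus_one_one(self, toy_b, toy_b_pathways):
        rng = np.random.default_rng(1)
        wt = {r: rng.normal() for r in toy_b.reaction_ids}
        muts = [{r: rng.normal() for r in toy_b.reaction_ids} for _ in range(5)]
        delta = pathway_delta(muts, wt, toy_b_pathways)
        assert np.all(delta >= -1.0) and np.all(delta <= 1.0)


class TestKnockoutFrequency:
    def test_counting(self):
        df = knockout_frequency([{"R_2"}, {"R_2", "R_s"}])
        freq = {row["combination"]: row["frequency"] for _, row in df.iterrows()}
        assert freq["R_2"] == 1.0
        assert freq["R_s"] == 0.5
        assert freq["R_2;R_s"] == 0.5

    def test_empty(self):
        assert knockout_frequency([]).empty

    def test_identical_strategies(self):
        df = knockout_frequency([{"a", "b"}] * 3)
        assert (df["frequency"] == 1.0).all()

    def test_sorted_descending(self):
        df = knockout_frequency([{"a"}, {"a", "b"}, {"c"}])
        assert list(df["frequency"]) == sorted(df["frequency"], reverse=True)


class TestBuildReport:
    def test_single_strategy_metrics(self, toy_b, criteria, toy_b_pathways):
        reports, summary = build_report(
            toy_b, [{"R_2"}], criteria, toy_b_pathways, substrate_id="R_s"
        )
        (rep,) = reports
        assert rep.max_growth == pytest.approx(10.0)
        assert rep.bpcy_value == pytest.approx(10.0)
        assert rep.robustness_high == pytest.approx(9.0)
        assert rep.robustness_low == pytest.approx(0.1)
        assert rep.coupling == "weak"
        assert summary["max_growth"]["mean"] == pytest.approx(10.0)

    def test_empty_set_warns(self, toy_b, criteria, caplog):
        with caplog.at_level("WARNING"):
            reports, summary = build_report(toy_b, [], criteria)
        assert reports == [] and summary == {}

    def test_fva_consistency_invariant(self, toy_b, criteria):
        from coupledesign.model_core import apply_knockouts
        from coupledesign.phenotype_sim import fva

        reports, _ = build_report(toy_b, [{"R_2"}], criteria, substrate_id="R_s")
        (rep,) = reports
        rng = fva(apply_knockouts(toy_b, {"R_2"}), fraction=0.9, reactions=["R_p"])
        assert rep.robustness_high <= rng["R_p"][1] + 1e-9
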