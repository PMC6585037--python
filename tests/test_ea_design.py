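import numpy as np
import pytest

from coupledesign.ea_design import (
    Candidate,
    EAConfig,
    default_knockout_pool,
    evaluate_candidate,
    run_ea,
    spea2_fitness,
    spea2_strength_raw,
    vary,
)


class TestEvaluateCandidate:
    def test_toy_b_wild_type_eaw(self, toy_b):
        cand = evaluate_candidate(toy_b, None, set(), "EAw", "R_p")
        assert cand.objectives == pytest.approx((10.0, 0.0))
        assert cand.feasible and cand.accepted

    def test_toy_b_knockout_eaw(self, toy_b):
        cand = evaluate_candidate(toy_b, None, {"R_2"}, "EAw", "R_p")
        assert cand.objectives == pytest.approx((10.0, 10.0))

    def test_toy_b_knockout_eam_accepted(self, toy_b):
        cand = evaluate_candidate(toy_b, None, {"R_2"}, "EAm", "R_p")
        assert cand.objectives[0] == pytest.approx(10.0)
        assert cand.objectives[1] == pytest.approx(10.0, rel=1e-4)
        assert cand.accepted

    def test_toy_b_wild_type_eam_rejected(self, toy_b):
        cand = evaluate_candidate(toy_b, None, set(), "EAm", "R_p")
        assert cand.feasible
        assert not cand.accepted  # product not forced at half-max growth

    def test_zero_growth_mutant_worst(self, toy_b):
        cand = evaluate_candidate(toy_b, None, {"R_1", "R_2"}, "EAw", "R_p")
        assert cand.objectives == (0.0, 0.0)
        assert not cand.feasible

    def test_unknown_formulation(self, toy_b):
        with pytest.raises(ValueError, match="formulation"):
            evaluate_candidate(toy_b, None, set(), "EAx", "R_p")


class TestSpea2Fitness:
    def test_hand_computed_strength_and_raw(self):
        objectives = [(1.0, 1.0), (2.0, 2.0), (1.0, 2.0)]  # A, B, C
        strength, raw = spea2_strength_raw(objectives)
        assert list(strength) == [0, 2, 1]
        assert list(raw) == [3.0, 0.0, 2.0]

    def test_single_candidate_raw_zero(self):
        _, raw = spea2_strength_raw([(1.0, 1.0)])
        assert raw[0] == 0.0

    def test_duplicates_mutually_non_dominating(self):
        strength, raw = spea2_strength_raw([(1.0, 1.0), (1.0, 1.0)])
        assert list(strength) == [0, 0]
        assert list(raw) == [0.0, 0.0]

    def test_nondominated_fitness_below_one(self):
        fit = spea2_fitness([(1.0, 1.0), (2.0, 2.0), (1.0, 2.0)])
        assert fit[1] < 1.0           # the dominator
        assert fit[0] > fit[1] and fit[2] > fit[1]

    def test_dominated_worse_than_some_dominator(self):
        rng = np.random.default_rng(3)
        objectives = [tuple(rng.uniform(0, 1, 2)) for _ in range(12)]
        fit = spea2_fitness(objectives)
        for i, oi in enumerate(objectives):
            dominators = [
                j for j, oj in enumerate(objectives)
                if all(a >= b for a, b in zip(oj, oi)) and oj != oi
            ]
            if dominators:
                assert any(fit[j] < fit[i] for j in dominators)


class TestVary:
    def _parents(self, kos):
        return [Candidate(knockouts=frozenset(k), objectives=(1.0, 1.0),
                          feasible=True, accepted=True) for k in kos]

    def test_remove_can_reach_empty_set(self):
        config = EAConfig(product_id="R_p", mutation_rate=1.0, crossover_rate=0.0)
        parents = self._parents([{"R_2"}])
        children = set()
        rng = np.random.default_rng(0)
        for _ in range(50):
            children.update(vary(parents, config, rng, pool=["R_1", "R_2", "R_3"]))
        assert frozenset() in children

    def test_crossover_child_subset_of_union(self):
        config = EAConfig(product_id="R_p", mutation_rate=0.0, crossover_rate=1.0)
        parents = self._parents([{"a", "b"}, {"b", "c"}])
        rng = np.random.default_rng(1)
        for child in vary(parents * 5, config, rng, pool=["a", "b", "c"]):
            assert child <= {"a", "b", "c"}

    def test_respects_max_knockouts(self):
        config = EAConfig(product_id="R_p", max_knockouts=2, mutation_rate=1.0)
        parents = self._parents([{"a", "b"}, {"c", "d"}])
        rng = np.random.default_rng(2)
        for child in vary(parents * 10, config, rng, pool=list("abcdef")):
            assert len(child) <= 2

    def test_fixed_seed_reproducible(self):
        config = EAConfig(product_id="R_p")
        parents = self._parents([{"a", "b"}, {"b", "c"}, {"d"}])
        out1 = vary(parents, config, np.random.default_rng(7), pool=list("abcde"))
        out2 = vary(parents, config, np.random.default_rng(7), pool=list("abcde"))
        assert out1 == out2

    def test_empty_parents_rejected(self):
        with pytest.raises(ValueError):
            vary([], EAConfig(product_id="R_p"), np.random.default_rng(0), ["a"])


def test_default_pool_excludes_pseudo_reactions(toy_b_maint):
    pool = default_knockout_pool(toy_b_maint)
    assert pool == ["R_1", "R_2", "R_3"]


class TestRunEA:
    def test_eam_recovers_forcing_knockout(self, toy_b):
        config = EAConfig(formulation="EAm", product_id="R_p", max_evaluations=500,
                          population_size=20, archive_size=20, seed=42)
        archive = run_ea(toy_b, None, config)
        assert frozenset({"R_2"}) in {c.knockouts for c in archive}

    def test_archive_mutually_non_dominated_and_accepted(self, toy_c):
        config = EAConfig(formulation="EAw", product_id="R_p", max_evaluations=400,
                          population_size=20, archive_size=20, seed=0)
        archive = run_ea(toy_c, None, config)
        assert archive
        objectives = [c.objectives for c in archive]
        for i, oi in enumerate(objectives):
            for j, oj in enumerate(objectives):
                if i != j:
                    assert not (
                        all(a >= b for a, b in zip(oj, oi))
                        and any(a > b for a, b in zip(oj, oi))
                    )
        assert all(c.accepted and c.feasible for c in archive)

    def test_zero_evaluation_budget_returns_initial_front(self, toy_b):
        config = EAConfig(formulation="EAw", product_id="R_p", max_evaluations=0,
                          population_size=10, archive_size=10, seed=5)
        archive = run_ea(toy_b, None, config)
        assert isinstance(archive, list)

    def test_bit_reproducible_with_seed(self, toy_b):
        config = EAConfig(formulation="EAw", product_id="R_p", max_evaluations=300,
                          population_size=15, archive_size=15, seed=11)
        a1 = run_ea(toy_b, None, config)
        a2 = run_ea(toy_b, None, config)
        assert [c.knockouts for c in a1] == [c.knockouts for c in a2]
        assert [c.objectives for c in a1] == [c.objectives for c in a2]

    def test_eam_archive_passes_acceptance_test(self, toy_b):
        from coupledesign.model_core import apply_knockouts
        from coupledesign.phenotype_sim import flux_extremum

        config = EAConfig(formulation="EAm", product_id="R_p", max_evaluations=300,
                          population_size=15, archive_size=15, seed=3)
        for cand in run_ea(toy_b, None, config):
            mut = apply_knockouts(toy_b, cand.knockouts)
            z = cand.objectives[0]
            half_min = flux_extremum(mut, "R_p", "min", extra_lb={"R_bio": z / 2})
            assert half_min is not None and half_min > 1e-6
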