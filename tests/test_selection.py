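"""The PADDS selection algorithm: scores, five-phase evaluation,
tie-breaking, full runs and the core set."""

import random

import pytest

from padds.ddi import CandidateDDI, PPINetwork, enumerate_candidates
from padds.selection import (
    PaddsConfig,
    PaddsSelection,
    SetMember,
    benefit,
    core_set,
    default_alpha_grid,
    reassessed_benefit,
    run_alpha_sweep,
    run_padds,
    tie_break,
    total_benefit,
)
from padds.simulate import simulate_recovery_study


class TestBenefit:
    def test_without_cooccurrence_equals_modified_association(self):
        from padds.ddi import modified_association

        assert benefit(4, 12, 0, 5, 0.5) == modified_association(4, 12, 0.5)

    def test_direct_evaluation(self):
        assert benefit(2, 0, 3, 3, 0.5) == pytest.approx(5.0)

    def test_cooccurrence_term_is_c_when_c_equals_maxc(self):
        assert benefit(1, 0, 7, 7, 0.0) == pytest.approx(1 + 7)

    def test_positive_c_without_maxc_rejected(self):
        with pytest.raises(ValueError):
            benefit(1, 0, 2, 0, 0.0)


class TestReassessedBenefit:
    def test_nothing_explained_keeps_benefit(self):
        assert reassessed_benefit(5.0, 4, 0, 0.01) == 5.0

    def test_fully_redundant_pair_is_penalized(self):
        assert reassessed_benefit(5.0, 4, 4, 0.01) == pytest.approx(-0.04)

    def test_partial_redundancy(self):
        assert reassessed_benefit(5.0, 4, 1, 0.01) == pytest.approx(3.74)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            reassessed_benefit(1.0, 0, 0, 0.01)


class TestTotalBenefit:
    def test_empty(self):
        assert total_benefit([]) == 0.0

    def test_all_original_members_sum_benefits(self):
        members = [SetMember(("a", "b"), 2.0, 1.0, "original"),
                   SetMember(("c", "d"), 3.0, 0.5, "original")]
        assert total_benefit(members) == 5.0

    def test_mixed_members(self):
        members = [
            SetMember(("a", "b"), 2.0, 2.0, "original"),
            SetMember(("c", "d"), 3.0, 1.5, "reassessed"),
            SetMember(("e", "f"), 4.0, -0.1, "reassessed"),
        ]
        assert total_benefit(members) == pytest.approx(2.0 + 1.5 - 0.1)


def _candidate(pair, O=1, N=0, C=0, ppis=None, multiplicity=0):
    ppis = frozenset(ppis if ppis is not None else {(f"x{k}", f"y{k}") for k in range(O)})
    return CandidateDDI(pair[0], pair[1], O, N, C, ppis, multiplicity)


class TestTieBreak:
    def test_minimum_n_wins_first(self):
        d1 = _candidate(("a", "b"), O=1, N=2)
        d2 = _candidate(("c", "d"), O=9, N=5, C=9)
        assert tie_break(d1, d2, random.Random(0)) is d1

    def test_maximum_o_breaks_equal_n(self):
        d1 = _candidate(("a", "b"), O=4, N=3)
        d2 = _candidate(("c", "d"), O=2, N=3)
        assert tie_break(d1, d2, random.Random(0)) is d1

    def test_multiplicity_breaks_equal_n_and_o(self):
        d1 = _candidate(("a", "b"), O=2, N=0, multiplicity=1)
        d2 = _candidate(("c", "d"), O=2, N=0, multiplicity=0)
        assert tie_break(d1, d2, random.Random(0)) is d1

    def test_full_tie_is_random_but_seeded(self):
        d1 = _candidate(("a", "b"), O=2, N=1)
        d2 = _candidate(("c", "d"), O=2, N=1)
        picks = {tie_break(d1, d2, random.Random(seed)).pair for seed in range(20)}
        assert picks == {("a", "b"), ("c", "d")}  # both reachable
        assert tie_break(d1, d2, random.Random(5)) is tie_break(
            d1, d2, random.Random(5)
        )


def _engine(annotations, edges, alpha=0.5, seed=0, proteins=None):
    net = PPINetwork.from_edges(edges, proteins=proteins)
    ctx = enumerate_candidates(net, annotations)
    return PaddsSelection(ctx, PaddsConfig(alpha=alpha, seed=seed)), net, ctx


class TestEvaluation:
    def test_unopposed_ddi_is_flagged_with_own_benefit(self):
        engine, _, ctx = _engine({"A": {"d1"}, "B": {"d2"}}, [("A", "B")])
        flagged, score = engine.evaluate_ddi(("d1", "d2"))
        assert flagged
        assert score == pytest.approx(engine.B[0])

    def test_interchangeable_alternatives_tie_at_ratio_one(self):
        """Two domain pairs with identical counts explaining the same
        interaction: neither side wins, the ratio is exactly 1."""
        engine, _, _ = _engine(
            {"A": {"d1", "d2"}, "B": {"d3", "d4"}}, [("A", "B")]
        )
        for pair in [("d1", "d3"), ("d1", "d4"), ("d2", "d3"), ("d2", "d4")]:
            flagged, score = engine.evaluate_ddi(pair)
            assert not flagged
            assert score == pytest.approx(1.0)

    def test_stronger_candidate_flagged_weaker_not(self):
        """One pair explains two interactions, its competitor only one of
        them: the strong pair wins its evaluation, the weak one loses."""
        annotations = {"A": {"i"}, "B": {"j", "v"}, "C": {"j"}}
        engine, _, _ = _engine(annotations, [("A", "B"), ("A", "C")])
        strong_flagged, _ = engine.evaluate_ddi(("i", "j"))
        weak_flagged, ratio = engine.evaluate_ddi(("i", "v"))
        assert strong_flagged and not weak_flagged
        assert 0 < ratio < 1

    def test_final_set_member_not_reevaluated(self):
        engine, _, _ = _engine({"A": {"d1"}, "B": {"d2"}}, [("A", "B")])
        engine.select_next()
        with pytest.raises(ValueError):
            engine.evaluate_ddi(("d1", "d2"))


class TestRunPadds:
    def test_single_domain_proteins_select_every_candidate(self):
        annotations = {p: {f"d{p}"} for p in "ABCD"}
        net = PPINetwork.from_edges([("A", "B"), ("C", "D"), ("A", "C")])
        result = run_padds(net, annotations, PaddsConfig(alpha=0.3, seed=0))
        assert sorted(result.pairs) == [("dA", "dB"), ("dA", "dC"), ("dC", "dD")]

    def test_every_explainable_interaction_covered(self):
        net, annotations, _ = simulate_recovery_study(seed=11, noise_edge_fraction=0.1)
        ctx = enumerate_candidates(net, annotations)
        result = run_padds(net, annotations, PaddsConfig(alpha=0.7, seed=2), context=ctx)
        covered = set()
        for s in result.ranked:
            covered |= set(s.candidate.explained_ppis)
        assert covered == set(ctx.explainers)

    def test_identical_runs_are_identical(self):
        net, annotations, _ = simulate_recovery_study(seed=5)
        r1 = run_padds(net, annotations, PaddsConfig(alpha=0.4, seed=9))
        r2 = run_padds(net, annotations, PaddsConfig(alpha=0.4, seed=9))
        assert r1.ranked == r2.ranked

    def test_planted_truth_recovered_without_noise(self):
        net, annotations, truth = simulate_recovery_study(seed=3)
        result = run_padds(net, annotations, PaddsConfig(alpha=0.2, seed=1))
        assert truth.true_ddis <= set(result.pairs)

    def test_alpha_zero_prefers_promiscuous_alpha_one_specific(self):
        """A pair explaining many interactions but carried by many
        non-interacting pairs outranks a clean pair at alpha = 0 and is
        outranked by it at alpha = 1."""
        annotations = {}
        edges = []
        for k in range(5):  # promiscuous pair: O = 5, N = 20
            annotations[f"a{k}"] = {"x1"}
            annotations[f"b{k}"] = {"x2"}
            edges.append((f"a{k}", f"b{k}"))
        for k in range(3):  # specific pair: O = 3, N = 0
            annotations[f"c{k}"] = {"y1"}
            edges.append((f"c{k}", "d0"))
        annotations["d0"] = {"y2"}
        net = PPINetwork.from_edges(edges)
        lax = run_padds(net, annotations, PaddsConfig(alpha=0.0, seed=0))
        strict = run_padds(net, annotations, PaddsConfig(alpha=1.0, seed=0))
        assert lax.pairs.index(("x1", "x2")) < lax.pairs.index(("y1", "y2"))
        assert strict.pairs.index(("y1", "y2")) < strict.pairs.index(("x1", "x2"))


class TestCoreSet:
    def test_single_run_is_its_own_core(self):
        net, annotations, _ = simulate_recovery_study(seed=7)
        result = run_padds(net, annotations, PaddsConfig(alpha=0.5, seed=0))
        assert core_set([result]) == set(result.pairs)

    def test_disjoint_sets_have_empty_core(self):
        assert core_set([[("a", "b")], [("c", "d")]]) == set()

    def test_core_matches_brute_force_intersection(self):
        net, annotations, _ = simulate_recovery_study(seed=2, noise_edge_fraction=0.2)
        sweep = run_alpha_sweep(net, annotations, alphas=(0.0, 0.5, 1.0), seed=4)
        expected = (
            set(sweep[0.0].pairs) & set(sweep[0.5].pairs) & set(sweep[1.0].pairs)
        )
        assert core_set(sweep.values()) == expected
        for result in sweep.values():
            assert core_set(sweep.values()) <= set(result.pairs)


def test_default_alpha_grid_endpoints():
    grid = default_alpha_grid()
    assert grid[0] == 0.0 and grid[-1] == 1.0 and len(grid) == 11
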