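"""Iterative pairing: assignment solver, confidence gaps, growth, seeding."""

import itertools

import numpy as np
import pytest

from copair.data_model import CoMSA, Matching
from copair.evaluation import tp_fraction
from copair.graph_alignment import GAConfig
from copair.ipa import (
    DCAScorer,
    IPAConfig,
    MIScorer,
    MirrorTreeScorer,
    ga_ipa,
    ipa_run,
    score_species,
    solve_assignment,
)
from copair.synthetic import SimConfig, simulate
from conftest import planted_duplicate_dataset


def brute_force_assignment(scores):
    n = scores.shape[0]
    best, best_total = None, -np.inf
    for perm in itertools.permutations(range(n)):
        total = sum(scores[r, perm[r]] for r in range(n))
        if total > best_total:
            best, best_total = perm, total
    return np.asarray(best), best_total


class TestSolveAssignment:
    def test_two_by_two_example(self):
        scores = np.array([[3.0, 1.0], [1.0, 2.0]])
        assignment, gaps = solve_assignment(scores)
        assert assignment.tolist() == [0, 1]  # total 5
        # forbidding (0,0) forces the off-diagonal total 1 + 1 = 2 -> gap 3
        assert gaps[0] == pytest.approx(3.0)
        assert gaps[1] == pytest.approx(3.0)

    def test_one_by_one_is_infinitely_confident(self):
        assignment, gaps = solve_assignment(np.array([[0.7]]))
        assert assignment.tolist() == [0]
        assert np.isinf(gaps[0])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_permutation_enumeration(self, n, rng):
        for _ in range(20):
            scores = rng.normal(size=(n, n))
            assignment, gaps = solve_assignment(scores)
            _, best_total = brute_force_assignment(scores)
            total = scores[np.arange(n), assignment].sum()
            assert total == pytest.approx(best_total)
            assert (gaps >= -1e-9).all()

    def test_column_permutation_equivariance(self, rng):
        scores = rng.normal(size=(5, 5))
        perm = rng.permutation(5)
        base, _ = solve_assignment(scores)
        permuted, _ = solve_assignment(scores[:, perm])
        assert (perm[permuted] == base).all()

    def test_degenerate_ties_give_valid_permutation(self):
        assignment, gaps = solve_assignment(np.ones((4, 4)))
        assert sorted(assignment.tolist()) == [0, 1, 2, 3]
        # all-equal scores: forbidding any pair costs nothing
        np.testing.assert_allclose(gaps, 0.0, atol=1e-6)

    def test_gap_matches_enumeration(self, rng):
        # assignment-level gap: optimal total minus optimal with pair banned
        scores = rng.normal(size=(4, 4))
        assignment, gaps = solve_assignment(scores)
        for r in range(4):
            totals = [
                sum(scores[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
                if p[r] != assignment[r]
            ]
            expected = scores[np.arange(4), assignment].sum() - max(totals)
            assert gaps[r] == pytest.approx(expected)


class TestScoreSpecies:
    def test_uses_model_and_excludes_gold(self):
        ds = planted_duplicate_dataset({"sp1": 3, "sp2": 2}, seed=1)
        comsa = CoMSA.from_matching(ds, ds.truth)
        scorer = MIScorer(pseudocount=0.5)
        scorer.fit(comsa)
        a_idx = ds.msa_a.species_index["sp1"]
        gold = [(a_idx[0], ds.truth[a_idx[0]])]
        sa = score_species(scorer, ds, "sp1", exclude=gold)
        assert sa.a_indices.size == 2
        assert a_idx[0] not in sa.a_indices
        assert sa.scores.shape == (2, 2)

    def test_empty_unresolved_rejected(self):
        ds = planted_duplicate_dataset({"sp1": 2, "sp2": 2}, seed=1)
        gold = [(a, ds.truth[a]) for a in ds.msa_a.species_index["sp1"]]
        scorer = MIScorer()
        scorer.fit(CoMSA.from_matching(ds, ds.truth))
        with pytest.raises(ValueError, match="unresolved"):
            score_species(scorer, ds, "sp1", exclude=gold)


class TestIpaRun:
    def test_all_singleton_species_need_one_fit(self):
        ds = planted_duplicate_dataset({f"sp{i}": 1 for i in range(8)}, seed=3)
        matching, state = ipa_run(ds, None, IPAConfig(model_kind="mi"))
        assert matching == ds.truth
        assert state.model_fits == 1
        assert tp_fraction(matching, ds.truth) == 1.0

    def test_full_truth_seed_is_returned_unchanged(self):
        ds = planted_duplicate_dataset({"sp1": 3, "sp2": 3}, seed=4)
        matching, state = ipa_run(ds, ds.truth.pairs(), IPAConfig())
        assert matching == ds.truth
        assert state.model_fits == 0

    def test_seed_pairs_left_untouched(self):
        out = simulate(SimConfig(n_species=10, n_copies=5, m_mean=3, l_a=20,
                                 l_b=20, seed=5))
        ds = out.dataset
        seed = ds.truth.pairs()[::4]
        matching, state = ipa_run(ds, seed, IPAConfig(model_kind="mi"))
        for a, b in seed:
            assert matching[a] == b
        assert state.seed_pairs == seed

    def test_duplicated_seed_indices_rejected(self):
        ds = planted_duplicate_dataset({"sp1": 3, "sp2": 2}, seed=6)
        a = ds.msa_a.species_index["sp1"][0]
        seed = [(a, ds.truth[a]), (a, ds.truth[a])]
        with pytest.raises(ValueError, match="duplicated"):
            ipa_run(ds, seed, IPAConfig())

    def test_termination_bound_and_monotone_gold(self):
        out = simulate(SimConfig(n_species=8, n_copies=5, m_mean=3, l_a=20,
                                 l_b=20, seed=7))
        ds = out.dataset
        cfg = IPAConfig(model_kind="mi", n_increment=4)
        matching, state = ipa_run(ds, None, cfg)
        assert state.iterations <= int(np.ceil(ds.depth / cfg.n_increment)) + 1
        assert len(state.gold_pairs) == ds.depth
        matching.validate_species(ds)

    def test_deterministic_given_seed(self):
        out = simulate(SimConfig(n_species=8, n_copies=5, m_mean=3, l_a=20,
                                 l_b=20, seed=8))
        ds = out.dataset
        m1, _ = ipa_run(ds, None, IPAConfig(model_kind="mi", seed=5))
        m2, _ = ipa_run(ds, None, IPAConfig(model_kind="mi", seed=5))
        assert m1 == m2

    def test_injected_scorer_matches_config_path(self):
        # the iteration machinery is score-agnostic: passing the DCA scorer
        # explicitly reproduces the configured run bit-for-bit
        out = simulate(SimConfig(n_species=6, n_copies=4, m_mean=2.5, l_a=15,
                                 l_b=15, seed=9))
        ds = out.dataset
        cfg = IPAConfig(model_kind="dca", seed=2)
        m1, _ = ipa_run(ds, None, cfg)
        m2, _ = ipa_run(ds, None, cfg, scorer=DCAScorer(0.5, 0.8))
        assert m1 == m2

    def test_mirrortree_scorer_pathway(self):
        out = simulate(SimConfig(n_species=8, n_copies=5, m_mean=3, l_a=25,
                                 l_b=25, seed=10))
        ds = out.dataset
        seed = ds.truth.pairs()[::3]
        matching, _ = ipa_run(ds, seed, IPAConfig(model_kind="mirrortree"))
        matching.validate_species(ds)
        assert tp_fraction(matching, ds.truth) > 0.5


class TestGaIpa:
    def test_noise_free_planted_dataset_recovered(self):
        ds = planted_duplicate_dataset(
            {f"sp{i}": 3 for i in range(6)}, length=60, seed=11, dispersed=True
        )
        matching = ga_ipa(
            ds,
            GAConfig(replicates=4, seed=0),
            IPAConfig(model_kind="mi"),
            k=3,
        )
        assert matching == ds.truth

    def test_strongly_coupled_dataset_high_tp(self):
        out = simulate(SimConfig(n_species=25, n_copies=6, m_mean=4, l_a=25,
                                 l_b=25, n_coupled=12, coupling_strength=0.9,
                                 seed=12))
        ds = out.dataset
        matching = ga_ipa(
            ds,
            GAConfig(replicates=4, seed=0, stall_factor=30),
            IPAConfig(model_kind="mi"),
            k=5,
        )
        assert tp_fraction(matching, ds.truth) >= 0.9
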