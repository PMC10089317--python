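"""Annealed graph alignment: cost, incremental deltas, recovery, robustness."""

import numpy as np
import pytest

from copair.data_model import Matching
from copair.graph_alignment import (
    GAConfig,
    GAResult,
    anneal,
    delta_cost,
    ga_cost,
    replicated_anneal,
    robust_pairs,
)
from copair.similarity_network import SimilarityNetwork, build_knn_network
from conftest import enumerate_matchings, naive_ga_cost, planted_duplicate_dataset


def nets_for(ds, k=3):
    return build_knn_network(ds.msa_a, k), build_knn_network(ds.msa_b, k)


@pytest.fixture(scope="module")
def planted():
    ds = planted_duplicate_dataset(
        {"sp1": 3, "sp2": 2, "sp3": 2}, length=60, seed=9, dispersed=True
    )
    na, nb = nets_for(ds)
    return ds, na, nb


class TestGACost:
    def test_empty_edge_set_costs_zero(self, planted):
        ds, _, nb = planted
        empty = SimilarityNetwork(
            n_nodes=ds.depth,
            edges=np.empty((0, 2), dtype=np.int64),
            distances=np.empty(0),
            weights=np.empty(0),
            scale=1.0,
            flavor="knn",
        )
        assert ga_cost(ds.truth, empty, nb) == 0.0

    def test_matches_enumeration_oracle(self, planted):
        ds, na, nb = planted
        for matching in enumerate_matchings(ds):
            assert ga_cost(matching, na, nb) == pytest.approx(
                naive_ga_cost(matching, na, nb), abs=1e-12
            )

    def test_planted_matching_is_global_minimum(self, planted):
        ds, na, nb = planted
        costs = {m: ga_cost(m, na, nb) for m in enumerate_matchings(ds)}
        best = min(costs, key=costs.get)
        assert best == ds.truth
        # exact copy: minimum equals -sum of squared A weights
        assert costs[best] == pytest.approx(-(na.weights**2).sum())

    def test_index_set_mismatch(self, planted):
        ds, na, nb = planted
        with pytest.raises(ValueError, match="index set"):
            ga_cost(Matching(np.arange(3)), na, nb)


class TestDeltaCost:
    def test_equals_full_recomputation(self, planted, rng):
        ds, na, nb = planted
        for _ in range(200):
            matching = ds.random_matching(rng)
            sp = list(ds.species_pairs())[rng.integers(3)]
            a_idx = ds.msa_a.species_index[sp]
            i, j = rng.choice(a_idx, size=2, replace=False)
            pi2 = matching.pi.copy()
            pi2[i], pi2[j] = pi2[j], pi2[i]
            expected = ga_cost(Matching(pi2), na, nb) - ga_cost(matching, na, nb)
            assert delta_cost(matching, i, j, na, nb) == pytest.approx(
                expected, abs=1e-9
            )

    def test_swap_and_swap_back_cancels(self, planted, rng):
        ds, na, nb = planted
        matching = ds.random_matching(rng)
        i, j = ds.msa_a.species_index["sp1"][:2]
        d1 = delta_cost(matching, i, j, na, nb)
        pi2 = matching.pi.copy()
        pi2[i], pi2[j] = pi2[j], pi2[i]
        d2 = delta_cost(Matching(pi2), i, j, na, nb)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    def test_isolated_nodes_give_zero(self, planted):
        ds, _, nb = planted
        empty = SimilarityNetwork(
            n_nodes=ds.depth,
            edges=np.empty((0, 2), dtype=np.int64),
            distances=np.empty(0),
            weights=np.empty(0),
            scale=1.0,
            flavor="knn",
        )
        i, j = ds.msa_a.species_index["sp1"][:2]
        assert delta_cost(ds.truth, i, j, empty, nb) == 0.0

    def test_cross_species_swap_rejected(self, planted):
        ds, na, nb = planted
        i = ds.msa_a.species_index["sp1"][0]
        j = ds.msa_a.species_index["sp2"][0]
        with pytest.raises(ValueError, match="different species"):
            delta_cost(ds.truth, i, j, na, nb, dataset=ds)


class TestAnneal:
    def test_exponential_schedule_value(self):
        # T(t) = T0 * alpha^t
        assert 10 * 0.9**2 == pytest.approx(8.1)

    def test_reaches_enumerated_optimum(self, planted):
        ds, na, nb = planted
        optimum = min(ga_cost(m, na, nb) for m in enumerate_matchings(ds))
        hits = 0
        for s in range(10):
            res = anneal(ds, na, nb, GAConfig(seed=s))
            assert res.cost == pytest.approx(ga_cost(res.matching, na, nb))
            if res.cost == pytest.approx(optimum, abs=1e-12):
                hits += 1
        assert hits >= 9

    def test_final_cost_not_above_initial(self, planted):
        ds, na, nb = planted
        for s in range(5):
            rng = np.random.default_rng(s)
            initial = ga_cost(ds.random_matching(np.random.default_rng(s)), na, nb)
            res = anneal(ds, na, nb, GAConfig(seed=s), rng=rng)
            assert res.cost <= initial + 1e-12

    def test_feasibility_preserved(self, planted):
        ds, na, nb = planted
        res = anneal(ds, na, nb, GAConfig(seed=0))
        res.matching.validate_species(ds)

    def test_all_singleton_species_forced(self):
        ds = planted_duplicate_dataset({"sp1": 1, "sp2": 1, "sp3": 1}, seed=2)
        na, nb = nets_for(ds, k=2)
        res = anneal(ds, na, nb, GAConfig(seed=0))
        assert res.matching == ds.truth  # only one feasible matching

    def test_trajectory_logged(self, planted):
        ds, na, nb = planted
        res = anneal(ds, na, nb, GAConfig(seed=0), log_trajectory=True)
        assert res.trajectory is not None and res.trajectory.shape[1] == 3
        temps = res.trajectory[:, 1]
        assert (np.diff(temps) < 0).all()  # strictly cooling


class TestRobustPairs:
    def test_all_identical_runs(self, planted):
        ds, na, nb = planted
        res = [GAResult(ds.truth, -1.0)] * 3
        robust = robust_pairs(res)
        assert len(robust) == ds.depth

    def test_one_two_cycle_difference(self, planted):
        ds, *_ = planted
        pi2 = ds.truth.pi.copy()
        i, j = ds.msa_a.species_index["sp1"][:2]
        pi2[i], pi2[j] = pi2[j], pi2[i]
        robust = robust_pairs([GAResult(ds.truth, 0.0), GAResult(Matching(pi2), 0.0)])
        assert len(robust) == ds.depth - 2

    def test_histogram_mass_conservation(self, planted):
        ds, na, nb = planted
        results = replicated_anneal(ds, na, nb, GAConfig(replicates=4, seed=5))
        robust = robust_pairs(results)
        hist = robust.histogram()
        assert sum(c * n for c, n in hist.items()) == 4 * ds.depth

    def test_requires_two_results(self, planted):
        ds, *_ = planted
        with pytest.raises(ValueError, match="two replicates"):
            robust_pairs([GAResult(ds.truth, 0.0)])

    def test_robust_subset_is_partial_injection(self, planted):
        ds, na, nb = planted
        results = replicated_anneal(ds, na, nb, GAConfig(replicates=4, seed=1))
        robust = robust_pairs(results)
        a_side = [a for a, _ in robust.pairs]
        b_side = [b for _, b in robust.pairs]
        assert len(set(a_side)) == len(a_side)
        assert len(set(b_side)) == len(b_side)

    def test_robust_pairs_at_least_as_precise_as_single_run(self):
        # noisy planted data: the consensus filters out unstable pairs
        ds = planted_duplicate_dataset(
            {f"sp{i}": 3 for i in range(8)}, length=60, seed=3, noise=12,
            dispersed=True,
        )
        na, nb = nets_for(ds, k=4)
        results = replicated_anneal(ds, na, nb, GAConfig(replicates=6, seed=0))
        truth = ds.truth.pi
        tps = [np.mean(r.matching.pi == truth) for r in results]
        robust = robust_pairs(results)
        assert len(robust) > 0
        robust_tp = np.mean([truth[a] == b for a, b in robust.pairs])
        assert robust_tp >= max(tps) - 1e-12
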