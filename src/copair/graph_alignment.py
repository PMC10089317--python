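"""Graph alignment of two sequence-similarity networks by simulated annealing.

The pairing is scored by the (negative) total weight of overlapping edges,

    C(pi) = - sum_{(m,n) in E_A} w^A_mn * w^B_{pi(m) pi(n)},

summed over family-A edges whose image under ``pi`` is a family-B edge.
Cross-species pairs carry an infinite penalty; here the penalty is enforced
structurally: the move set (partner exchange between two pairs of the same
species) can never create a cross-species pair, so every visited matching is
feasible and the penalty term never fires.

Annealing follows the exponential cooling schedule ``T(t) = T0 * alpha^t``;
at each temperature level, proposed partner exchanges are accepted with
Metropolis probability ``min{1, exp[(C(pi) - C(pi')) / T]}`` until a fixed
acceptance quota is met (with a stall guard so frozen levels cool anyway).
Replicates differing only in their RNG stream are combined into *robust
pairs* — pairs proposed identically in every run — which are empirically far
more precise than any single run.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import Matching, PairedDataset
from .similarity_network import SimilarityNetwork

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class GAConfig:
    """Annealing schedule and replication settings.

    ``t0=None`` selects the initial temperature automatically as the 95th
    percentile of |delta C| over 1000 random proposed swaps on the initial
    matching, so early moves are accepted nearly uniformly.  The quota
    defaults to ``10 * M`` accepted moves per level, and the run stops when
    ``T <= t_stop`` (default ``1e-4 * T0``).
    """

    t0: Optional[float] = None
    alpha: float = 0.95
    accepted_per_level: Optional[int] = None
    t_stop: Optional[float] = None
    t_stop_ratio: float = 1e-4
    stall_factor: int = 100
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.t_stop is not None and self.t0 is not None and self.t_stop >= self.t0:
            raise ValueError("t_stop must be below t0")


@dataclass
class GAResult:
    """Final matching of one annealing run with its exact cost."""

    matching: Matching
    cost: float
    trajectory: Optional[np.ndarray] = None  # columns (t, T, C)


@dataclass
class RobustPairSet:
    """Pairs predicted identically in every replicate, plus the occurrence
    histogram of all candidate pairs."""

    pairs: list[tuple[int, int]]
    replicates: int
    occurrences: Counter

    def histogram(self) -> dict[int, int]:
        """Map (number of runs a pair appeared in) -> (number of such pairs)."""
        hist: Counter = Counter(self.occurrences.values())
        return dict(sorted(hist.items()))

    def __len__(self) -> int:
        return len(self.pairs)


def ga_cost(
    matching: Matching,
    net_a: SimilarityNetwork,
    net_b: SimilarityNetwork,
) -> float:
    """Exact graph-alignment cost of a matching (non-positive)."""
    if net_a.n_nodes != net_b.n_nodes or net_a.n_nodes != matching.m:
        raise ValueError("networks and matching must share one index set")
    wb = net_b.dense_weights()
    pi = matching.pi
    ea = net_a.edges
    if ea.size == 0:
        return 0.0
    return float(-(net_a.weights * wb[pi[ea[:, 0]], pi[ea[:, 1]]]).sum())


def delta_cost(
    matching: Matching,
    i: int,
    j: int,
    net_a: SimilarityNetwork,
    net_b: SimilarityNetwork,
    dataset: Optional[PairedDataset] = None,
    _wb: Optional[np.ndarray] = None,
    _csr: Optional[tuple] = None,
) -> float:
    """Cost change of exchanging the partners of A-sequences ``i`` and ``j``.

    Touches only edges incident to the two A nodes; equals
    ``ga_cost(pi') - ga_cost(pi)``.  ``i`` and ``j`` must share a species
    (checked when a dataset is supplied).
    """
    if dataset is not None:
        spa = dataset.msa_a.species
        if spa[i] != spa[j]:
            raise ValueError(f"A-sequences {i} and {j} belong to different species")
    wb = net_b.dense_weights() if _wb is None else _wb
    indptr, nbr, wts = net_a.adjacency_csr() if _csr is None else _csr
    pi = matching.pi
    pii, pij = pi[i], pi[j]
    delta = 0.0
    for e in range(indptr[i], indptr[i + 1]):
        n = nbr[e]
        if n == j:
            continue  # the i-j edge maps to the same B pair after the swap
        delta -= wts[e] * (wb[pij, pi[n]] - wb[pii, pi[n]])
    for e in range(indptr[j], indptr[j + 1]):
        n = nbr[e]
        if n == i:
            continue
        delta -= wts[e] * (wb[pii, pi[n]] - wb[pij, pi[n]])
    return float(delta)


@njit(cache=True)
def _anneal_kernel(
    pi,
    indptr,
    nbr,
    wts,
    wb,
    eligible,
    memb_flat,
    memb_indptr,
    memb_of,
    t0,
    alpha,
    t_stop,
    quota,
    stall_factor,
    seed,
    c0,
):  # pragma: no cover - compiled
    np.random.seed(seed)
    cost = c0
    n_levels = 0
    t = t0
    while t > t_stop:
        n_levels += 1
        t *= alpha
    level_t = np.empty(n_levels)
    level_c = np.empty(n_levels)
    t = t0
    max_attempts = stall_factor * quota
    frozen = 0
    done = 0
    for level in range(n_levels):
        accepted = 0
        attempts = 0
        while accepted < quota and attempts < max_attempts:
            attempts += 1
            i = eligible[np.random.randint(eligible.shape[0])]
            s = memb_of[i]
            lo = memb_indptr[s]
            hi = memb_indptr[s + 1]
            j = memb_flat[lo + np.random.randint(hi - lo)]
            while j == i:
                j = memb_flat[lo + np.random.randint(hi - lo)]
            pii = pi[i]
            pij = pi[j]
            delta = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                n = nbr[e]
                if n == j:
                    continue
                delta -= wts[e] * (wb[pij, pi[n]] - wb[pii, pi[n]])
            for e in range(indptr[j], indptr[j + 1]):
                n = nbr[e]
                if n == i:
                    continue
                delta -= wts[e] * (wb[pii, pi[n]] - wb[pij, pi[n]])
            if delta <= 0.0 or np.random.random() < np.exp(-delta / t):
                pi[i] = pij
                pi[j] = pii
                cost += delta
                accepted += 1
        level_t[level] = t
        level_c[level] = cost
        done = level + 1
        t *= alpha
        if accepted == 0:
            frozen += 1
            if frozen >= 3:  # system frozen: no move accepted for 3 levels
                break
        else:
            frozen = 0
    return pi, level_t[:done], level_c[:done]


def _anneal_python(
    pi, indptr, nbr, wts, wb, eligible, memb_flat, memb_indptr, memb_of,
    t0, alpha, t_stop, quota, stall_factor, seed, c0,
):
    """Pure-python fallback with the same semantics as the compiled kernel."""
    rs = np.random.RandomState(seed)
    cost = c0
    levels_t, levels_c = [], []
    t = t0
    max_attempts = stall_factor * quota
    frozen = 0
    while t > t_stop:
        accepted = attempts = 0
        while accepted < quota and attempts < max_attempts:
            attempts += 1
            i = eligible[rs.randint(eligible.shape[0])]
            s = memb_of[i]
            lo, hi = memb_indptr[s], memb_indptr[s + 1]
            j = memb_flat[lo + rs.randint(hi - lo)]
            while j == i:
                j = memb_flat[lo + rs.randint(hi - lo)]
            pii, pij = pi[i], pi[j]
            delta = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                n = nbr[e]
                if n != j:
                    delta -= wts[e] * (wb[pij, pi[n]] - wb[pii, pi[n]])
            for e in range(indptr[j], indptr[j + 1]):
                n = nbr[e]
                if n != i:
                    delta -= wts[e] * (wb[pii, pi[n]] - wb[pij, pi[n]])
            if delta <= 0.0 or rs.random_sample() < np.exp(-delta / t):
                pi[i], pi[j] = pij, pii
                cost += delta
                accepted += 1
        levels_t.append(t)
        levels_c.append(cost)
        t *= alpha
        frozen = frozen + 1 if accepted == 0 else 0
        if frozen >= 3:
            break
    return pi, np.asarray(levels_t), np.asarray(levels_c)


def _species_arrays(dataset: PairedDataset):
    """Flattened per-species A-index membership and eligibility arrays."""
    memb_of = np.empty(dataset.depth, dtype=np.int64)
    memb_flat = []
    memb_indptr = [0]
    eligible = []
    for s, (a_idx, _) in enumerate(dataset.species_pairs().values()):
        memb_of[a_idx] = s
        memb_flat.extend(a_idx.tolist())
        memb_indptr.append(memb_indptr[-1] + a_idx.size)
        if a_idx.size >= 2:
            eligible.extend(a_idx.tolist())
    return (
        np.asarray(memb_flat, dtype=np.int64),
        np.asarray(memb_indptr, dtype=np.int64),
        memb_of,
        np.asarray(eligible, dtype=np.int64),
    )


def _auto_t0(pi, csr, wb, eligible, memb_flat, memb_indptr, memb_of, rng, n_probe=1000):
    """95th percentile of |delta C| over random proposed swaps."""
    indptr, nbr, wts = csr
    deltas = np.empty(n_probe)
    for p in range(n_probe):
        i = eligible[rng.integers(eligible.size)]
        s = memb_of[i]
        lo, hi = memb_indptr[s], memb_indptr[s + 1]
        j = memb_flat[lo + rng.integers(hi - lo)]
        while j == i:
            j = memb_flat[lo + rng.integers(hi - lo)]
        pii, pij = pi[i], pi[j]
        d = 0.0
        for e in range(indptr[i], indptr[i + 1]):
            n = nbr[e]
            if n != j:
                d -= wts[e] * (wb[pij, pi[n]] - wb[pii, pi[n]])
        for e in range(indptr[j], indptr[j + 1]):
            n = nbr[e]
            if n != i:
                d -= wts[e] * (wb[pii, pi[n]] - wb[pij, pi[n]])
        deltas[p] = abs(d)
    t0 = float(np.percentile(deltas, 95))
    return t0 if t0 > 0 else 1.0


def anneal(
    dataset: PairedDataset,
    net_a: SimilarityNetwork,
    net_b: SimilarityNetwork,
    config: GAConfig,
    rng: Optional[np.random.Generator] = None,
    log_trajectory: bool = False,
) -> GAResult:
    """One simulated-annealing run from a random within-species matching."""
    if net_a.n_nodes != dataset.depth or net_b.n_nodes != dataset.depth:
        raise ValueError("networks must cover the dataset's index set")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pi = dataset.random_matching(rng).pi.copy()
    memb_flat, memb_indptr, memb_of, eligible = _species_arrays(dataset)
    if eligible.size == 0:
        # every species has a single pair: the matching is forced
        matching = Matching(pi)
        return GAResult(matching, ga_cost(matching, net_a, net_b))
    csr = net_a.adjacency_csr()
    wb = net_b.dense_weights()
    c0 = ga_cost(Matching(pi), net_a, net_b)
    t0 = config.t0 if config.t0 is not None else _auto_t0(
        pi, csr, wb, eligible, memb_flat, memb_indptr, memb_of, rng
    )
    t_stop = config.t_stop if config.t_stop is not None else config.t_stop_ratio * t0
    quota = (
        config.accepted_per_level
        if config.accepted_per_level is not None
        else 10 * dataset.depth
    )
    kernel = _anneal_kernel if _HAVE_NUMBA else _anneal_python
    kernel_seed = int(rng.integers(2**31 - 1))
    pi, level_t, level_c = kernel(
        pi,
        csr[0],
        csr[1],
        csr[2],
        wb,
        eligible,
        memb_flat,
        memb_indptr,
        memb_of,
        float(t0),
        float(config.alpha),
        float(t_stop),
        int(quota),
        int(config.stall_factor),
        kernel_seed,
        float(c0),
    )
    matching = Matching(pi)
    cost = ga_cost(matching, net_a, net_b)  # exact recomputation
    traj = None
    if log_trajectory:
        traj = np.column_stack([np.arange(level_t.size), level_t, level_c])
    return GAResult(matching, cost, traj)


def replicated_anneal(
    dataset: PairedDataset,
    net_a: SimilarityNetwork,
    net_b: SimilarityNetwork,
    config: GAConfig,
) -> list[GAResult]:
    """Independent annealing replicates differing only in their RNG stream."""
    results = []
    for r in range(config.replicates):
        rng = np.random.default_rng((config.seed, r))
        results.append(anneal(dataset, net_a, net_b, config, rng=rng))
    return results


def robust_pairs(results: Sequence[GAResult]) -> RobustPairSet:
    """Pairs (m, pi(m)) identical across all replicates, with the occurrence
    histogram of every candidate pair."""
    if len(results) < 2:
        raise ValueError("need at least two replicates to define robustness")
    m = results[0].matching.m
    if any(r.matching.m != m for r in results):
        raise ValueError("replicates cover different index sets")
    occ: Counter = Counter()
    for res in results:
        occ.update(res.matching.pairs())
    r = len(results)
    pairs = sorted(p for p, c in occ.items() if c == r)
    return RobustPairSet(pairs=pairs, replicates=r, occurrences=occ)
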