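"""MirrorTree-style baselines for paralog pairing.

MirrorTree methods compare the pairwise distance matrices of two protein
families: similar matrices (after reordering one family by the candidate
pairing) indicate matched phylogenies.  Here the similarity is the Pearson
correlation between all off-diagonal entries of the two Hamming-distance
matrices, and the pairing that maximises it is sought by the same
within-species partner-exchange Monte Carlo (Metropolis acceptance on the
negated score, exponential cooling) used for graph alignment.  Replicate
consensus yields MirrorTree robust pairs exactly as for graph alignment.

The per-pair MirrorTree score used inside the IPA (distance-profile Pearson
correlation to a training co-MSA) lives in
:class:`copair.ipa.MirrorTreeScorer`; the plain profile correlation is
exposed here as :func:`mirrortree_pair_score`.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .data_model import LabeledMSA, Matching, PairedDataset, pairwise_hamming
from .graph_alignment import GAConfig, GAResult, _species_arrays


def _upper_entries(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, k=1)


def mirrortree_score(
    d_a: np.ndarray, d_b: np.ndarray, matching: Matching
) -> float:
    """Pearson correlation between ``d_A`` and the matching-reordered
    ``d_B`` over all off-diagonal entries; in [-1, 1]."""
    d_a = np.asarray(d_a, dtype=np.float64)
    d_b = np.asarray(d_b, dtype=np.float64)
    if d_a.shape != d_b.shape or d_a.shape[0] != matching.m:
        raise ValueError("distance matrices and matching must share one index set")
    iu, ju = _upper_entries(matching.m)
    x = d_a[iu, ju]
    y = d_b[matching.pi[iu], matching.pi[ju]]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance matrix: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mirrortree_pair_score(a_profile: np.ndarray, b_profile: np.ndarray) -> float:
    """Pearson correlation of two distance profiles (to a shared training
    co-MSA); a constant profile yields -inf with a warning."""
    a = np.asarray(a_profile, dtype=np.float64)
    b = np.asarray(b_profile, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length vectors")
    if a.size < 3:
        raise ValueError("profiles need at least 3 training entries")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant distance profile; score undefined, using -inf")
        return float("-inf")
    return float(np.corrcoef(a, b)[0, 1])


def mirrortree_optimize(
    dataset: PairedDataset,
    config: Optional[GAConfig] = None,
    d_a: Optional[np.ndarray] = None,
    d_b: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> GAResult:
    """Maximise the MirrorTree score over within-species matchings by
    simulated annealing (same move set and cooling schedule as graph
    alignment).  Returns a :class:`GAResult` whose ``cost`` is the negated
    score, so replicate consensus via
    :func:`copair.graph_alignment.robust_pairs` applies unchanged."""
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d_a = pairwise_hamming(dataset.msa_a) if d_a is None else np.asarray(d_a, float)
    d_b = pairwise_hamming(dataset.msa_b) if d_b is None else np.asarray(d_b, float)
    d_a = d_a.astype(np.float64)
    d_b = d_b.astype(np.float64)
    m = dataset.depth
    pi = dataset.random_matching(rng).pi.copy()
    memb_flat, memb_indptr, memb_of, eligible = _species_arrays(dataset)
    n_pairs = m * (m - 1) // 2
    iu, ju = _upper_entries(m)
    x = d_a[iu, ju]
    sx = x.sum()
    sxx = (x * x).sum()
    var_x = n_pairs * sxx - sx * sx
    if var_x == 0:
        raise ValueError("zero-variance distance matrix: correlation undefined")

    # sufficient statistics of y = reordered d_B; row sums let us update the
    # Pearson correlation in O(M) per proposed swap
    def full_stats(pi):
        y = d_b[pi[iu], pi[ju]]
        return y.sum(), (y * y).sum(), (x * y).sum()

    sy, syy, sxy = full_stats(pi)

    def score(sy, syy, sxy):
        var_y = n_pairs * syy - sy * sy
        if var_y <= 0:
            raise ValueError("zero-variance distance matrix: correlation undefined")
        return (n_pairs * sxy - sx * sy) / np.sqrt(var_x * var_y)

    def swap_stats(pi, i, j, sy, syy, sxy):
        """Statistics after exchanging the partners of A-nodes i and j.

        The swap permutes y values between entries, so Sy and Syy are
        invariant; only Sxy changes, by
        ``sum_{n not in {i,j}} (dA[i,n] - dA[j,n]) (dB[pi_j,pi_n] - dB[pi_i,pi_n])``
        (the (i, j) entry itself is invariant by symmetry of dB).
        """
        u = d_a[i] - d_a[j]
        v = d_b[pi[j]][pi] - d_b[pi[i]][pi]
        d_sxy = float(u @ v) + 2.0 * d_a[i, j] * d_b[pi[i], pi[j]]
        return sy, syy, sxy + d_sxy

    if eligible.size == 0:
        matching = Matching(pi)
        return GAResult(matching, -mirrortree_score(d_a, d_b, matching))

    current = score(sy, syy, sxy)
    # automatic T0: 95th percentile of |delta cost| over random proposals
    if config.t0 is None:
        probes = []
        for _ in range(min(1000, 20 * m)):
            i = eligible[rng.integers(eligible.size)]
            s = memb_of[i]
            lo, hi = memb_indptr[s], memb_indptr[s + 1]
            j = memb_flat[lo + rng.integers(hi - lo)]
            while j == i:
                j = memb_flat[lo + rng.integers(hi - lo)]
            probes.append(abs(score(*swap_stats(pi, i, j, sy, syy, sxy)) - current))
        t0 = float(np.percentile(probes, 95)) or 1.0
    else:
        t0 = config.t0
    t_stop = config.t_stop if config.t_stop is not None else config.t_stop_ratio * t0
    quota = config.accepted_per_level if config.accepted_per_level is not None else 10 * m
    max_attempts = config.stall_factor * quota
    t = t0
    frozen = 0
    while t > t_stop:
        accepted = attempts = 0
        while accepted < quota and attempts < max_attempts:
            attempts += 1
            i = eligible[rng.integers(eligible.size)]
            s = memb_of[i]
            lo, hi = memb_indptr[s], memb_indptr[s + 1]
            j = memb_flat[lo + rng.integers(hi - lo)]
            while j == i:
                j = memb_flat[lo + rng.integers(hi - lo)]
            nsy, nsyy, nsxy = swap_stats(pi, i, j, sy, syy, sxy)
            delta_cost = current - score(nsy, nsyy, nsxy)  # cost = -score
            if delta_cost <= 0 or rng.random() < np.exp(-delta_cost / t):
                pi[i], pi[j] = pi[j], pi[i]
                sy, syy, sxy = nsy, nsyy, nsxy
                current = score(sy, syy, sxy)
                accepted += 1
        t *= config.alpha
        frozen = frozen + 1 if accepted == 0 else 0
        if frozen >= 3:  # system frozen: no accepted move for 3 levels
            break
    matching = Matching(pi)
    return GAResult(matching, -mirrortree_score(d_a, d_b, matching))


def replicated_mirrortree(
    dataset: PairedDataset, config: Optional[GAConfig] = None
) -> list[GAResult]:
    """Independent MirrorTree optimisations differing only by RNG stream."""
    config = config or GAConfig()
    d_a = pairwise_hamming(dataset.msa_a)
    d_b = pairwise_hamming(dataset.msa_b)
    out = []
    for r in range(config.replicates):
        rng = np.random.default_rng((config.seed, r))
        out.append(mirrortree_optimize(dataset, config, d_a=d_a, d_b=d_b, rng=rng))
    return out
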