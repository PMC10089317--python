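"""Iterative pairing algorithm (IPA) and the combined GA-IPA pipeline.

The IPA alternates between (i) fitting a pair-scoring model (DCA, PMI, or a
distance-profile correlation score) on a trusted "gold standard" co-MSA and
(ii) re-pairing: within every species, candidate A-B pairs are scored, an
optimal one-to-one assignment is solved, and each proposed pair receives a
*confidence gap* — the optimal assignment total minus the best total with
that pair forbidden.  The highest-confidence proposals are promoted into the
gold standard, growing it by ``n_increment`` pairs per iteration until the
co-MSA is complete.

Two modes exist.  In *seeded* mode the seed pairs (e.g. the robust pairs of
replicated graph alignment) are frozen: they are never re-scored or removed,
and promoted pairs accumulate monotonically.  In *seedless* mode the first
model is fit on a random within-species matching, all pairs are re-scored
and re-assigned at every iteration, and the gold standard is re-selected as
the current top-confidence pairs (its size still grows by ``n_increment``
per iteration).

``ga_ipa`` chains the two stages: replicated graph alignment, robust-pair
extraction, then seeded IPA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .coevolution import (
    CouplingModel,
    fit_dca,
    fit_pmi,
    sequence_weights,
)
from .data_model import CoMSA, Matching, PairedDataset
from .graph_alignment import (
    GAConfig,
    RobustPairSet,
    replicated_anneal,
    robust_pairs,
)
from .similarity_network import build_network


@dataclass
class IPAConfig:
    """IPA settings: increment size, score model and its hyperparameters."""

    n_increment: int = 6
    model_kind: str = "dca"  # "dca" | "mi" | "mirrortree"
    pseudocount: float = 0.5
    identity_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_increment < 1:
            raise ValueError("n_increment must be >= 1")
        if self.model_kind not in ("dca", "mi", "mirrortree"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")


@dataclass
class ScoredAssignment:
    """Per-species score matrix, optimal assignment, and confidence gaps.

    ``assignment[r]`` is the column (position into ``b_indices``) assigned
    to row r; ``gaps[r]`` is the assignment-level confidence of that pair.
    """

    species: str
    a_indices: np.ndarray
    b_indices: np.ndarray
    scores: np.ndarray
    assignment: np.ndarray
    gaps: np.ndarray

    def proposed_pairs(self) -> list[tuple[int, int, float]]:
        """(A index, B index, gap) triples for the chosen assignment."""
        return [
            (int(self.a_indices[r]), int(self.b_indices[self.assignment[r]]), float(self.gaps[r]))
            for r in range(self.a_indices.size)
        ]


class Scorer(Protocol):
    """Pair-scoring strategy: fit on a training co-MSA, then produce a
    larger-is-better score matrix for candidate A rows x B rows."""

    def fit(self, comsa: CoMSA) -> None: ...

    def score_matrix(self, a_codes: np.ndarray, b_codes: np.ndarray) -> np.ndarray: ...


class DCAScorer:
    """Mean-field DCA energies (negated, so larger is better)."""

    def __init__(self, pseudocount: float = 0.5, identity_threshold: float = 0.8):
        self.pseudocount = pseudocount
        self.identity_threshold = identity_threshold
        self.model: Optional[CouplingModel] = None

    def fit(self, comsa: CoMSA) -> None:
        wc = sequence_weights(comsa, self.identity_threshold)
        self.model = fit_dca(wc, self.pseudocount)

    def score_matrix(self, a_codes, b_codes) -> np.ndarray:
        assert self.model is not None, "call fit first"
        return self.model.score_matrix(a_codes, b_codes)


class MIScorer(DCAScorer):
    """Summed pointwise mutual information."""

    def fit(self, comsa: CoMSA) -> None:
        wc = sequence_weights(comsa, self.identity_threshold)
        self.model = fit_pmi(wc, self.pseudocount)


class MirrorTreeScorer:
    """Distance-profile correlation score.

    A candidate A sequence is described by its vector of Hamming distances to
    the training co-MSA's A halves, and likewise for B; the pair score is the
    Pearson correlation of the two profiles.  Constant profiles score -inf
    (with a warning), as the correlation is undefined there.
    """

    def __init__(self, **_ignored):
        self.train_a: Optional[np.ndarray] = None
        self.train_b: Optional[np.ndarray] = None

    def fit(self, comsa: CoMSA) -> None:
        self.train_a = comsa.codes[:, : comsa.l_a]
        self.train_b = comsa.codes[:, comsa.l_a :]

    def _profiles(self, codes: np.ndarray, train: np.ndarray) -> np.ndarray:
        d = cdist(codes, train, metric="hamming") * train.shape[1]
        centered = d - d.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        flat = norms == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} constant distance profiles; scoring them -inf",
                stacklevel=2,
            )
        norms[flat] = 1.0
        out = centered / norms[:, None]
        out[flat] = np.nan  # marker; turned into -inf in score_matrix
        return out

    def score_matrix(self, a_codes, b_codes) -> np.ndarray:
        assert self.train_a is not None, "call fit first"
        pa = self._profiles(np.atleast_2d(a_codes), self.train_a)
        pb = self._profiles(np.atleast_2d(b_codes), self.train_b)
        scores = pa @ pb.T
        scores[np.isnan(scores)] = -np.inf
        return scores


def get_scorer(config: IPAConfig) -> Scorer:
    if config.model_kind == "dca":
        return DCAScorer(config.pseudocount, config.identity_threshold)
    if config.model_kind == "mi":
        return MIScorer(config.pseudocount, config.identity_threshold)
    return MirrorTreeScorer()


def solve_assignment(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one assignment (maximising total score) plus per-pair
    confidence gaps.

    The gap of a chosen pair is the optimal total minus the best achievable
    total with that pair forbidden; for a 1x1 matrix it is +inf.  Exact ties
    are broken toward the lexicographically smallest assignment by a
    hierarchical perturbation far below the score resolution.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if scores.shape[0] != scores.shape[1]:
        raise ValueError("score matrix must be square (balanced pairing)")
    if n == 1:
        return np.zeros(1, dtype=np.int64), np.full(1, np.inf)
    neg = -1e150  # finite stand-in for -inf, keeps the LAP solver feasible
    finite_mask = np.isfinite(scores)
    finite = scores[finite_mask]
    span = float(np.abs(finite).max()) + 1.0 if finite.size else 1.0
    base = 2.0 * n
    tie = span * 1e-9 * (base ** -np.arange(n))[:, None] * (n - np.arange(n))[None, :] / n
    clipped = np.where(finite_mask, scores, neg)
    work = np.where(finite_mask, scores + tie, neg)
    rows, cols = linear_sum_assignment(work, maximize=True)
    assignment = np.empty(n, dtype=np.int64)
    assignment[rows] = cols
    total = float(clipped[rows, assignment[rows]].sum())
    gaps = np.empty(n)
    for r in range(n):
        forbidden = clipped.copy()
        forbidden[r, assignment[r]] = neg
        rr, cc = linear_sum_assignment(forbidden, maximize=True)
        alt = float(forbidden[rr, cc].sum())
        gaps[r] = np.inf if alt < neg / 2 else total - alt
    return assignment, gaps


def score_species(
    model,
    dataset: PairedDataset,
    species: str,
    exclude: Sequence[tuple[int, int]] = (),
) -> ScoredAssignment:
    """Score and optimally assign the unresolved A-B pairs of one species.

    ``model`` is anything exposing ``score_matrix`` (a fitted
    :class:`~copair.coevolution.CouplingModel` or a :class:`Scorer`);
    ``exclude`` lists gold-standard (A, B) index pairs to leave out.
    """
    a_idx, b_idx = dataset.species_pairs()[species]
    used_a = {a for a, _ in exclude}
    used_b = {b for _, b in exclude}
    a_idx = np.asarray([a for a in a_idx if a not in used_a], dtype=np.int64)
    b_idx = np.asarray([b for b in b_idx if b not in used_b], dtype=np.int64)
    if a_idx.size == 0 or a_idx.size != b_idx.size:
        raise ValueError(f"species {species!r} has no (balanced) unresolved pairs")
    scores = model.score_matrix(dataset.msa_a.codes[a_idx], dataset.msa_b.codes[b_idx])
    assignment, gaps = solve_assignment(scores)
    return ScoredAssignment(species, a_idx, b_idx, scores, assignment, gaps)


@dataclass
class IPAState:
    """Bookkeeping of one IPA run."""

    gold_pairs: list[tuple[int, int]]
    seed_pairs: list[tuple[int, int]]
    iterations: int
    model_fits: int
    tp_trajectory: list[float] = field(default_factory=list)


def _as_index_pairs(seed, dataset: PairedDataset) -> list[tuple[int, int]]:
    if seed is None:
        return []
    if isinstance(seed, RobustPairSet):
        return list(seed.pairs)
    if isinstance(seed, CoMSA):
        if seed.index_pairs is None:
            raise ValueError("seed co-MSA does not carry dataset indices")
        return list(seed.index_pairs)
    return [(int(a), int(b)) for a, b in seed]


def _check_seed(pairs: list[tuple[int, int]], dataset: PairedDataset) -> None:
    a_seen = [a for a, _ in pairs]
    b_seen = [b for _, b in pairs]
    if len(set(a_seen)) != len(a_seen) or len(set(b_seen)) != len(b_seen):
        raise ValueError("seed contains duplicated A or B indices")
    spa, spb = dataset.msa_a.species, dataset.msa_b.species
    for a, b in pairs:
        if spa[a] != spb[b]:
            raise ValueError(f"seed pair ({a}, {b}) crosses species")


def _record_tp(dataset, pairs, state) -> None:
    if dataset.truth is None:
        return
    truth = dataset.truth.pi
    correct = sum(1 for a, b in pairs if truth[a] == b)
    state.tp_trajectory.append(correct / dataset.depth)


def ipa_run(
    dataset: PairedDataset,
    seed: Optional[object] = None,
    config: Optional[IPAConfig] = None,
    scorer: Optional[Scorer] = None,
) -> tuple[Matching, IPAState]:
    """Run the iterative pairing algorithm.

    ``seed`` may be ``None`` (seedless mode), a :class:`RobustPairSet`, a
    seed :class:`CoMSA` built from this dataset, or an iterable of (A, B)
    index pairs.  A custom ``scorer`` overrides ``config.model_kind``.
    """
    config = config or IPAConfig()
    scorer = scorer if scorer is not None else get_scorer(config)
    seed_pairs = _as_index_pairs(seed, dataset)
    _check_seed(seed_pairs, dataset)
    m = dataset.depth
    if len(seed_pairs) == m:
        # complete seed: nothing to infer, the seed is the answer
        pi = np.empty(m, dtype=np.int64)
        for a, b in seed_pairs:
            pi[a] = b
        state = IPAState(list(seed_pairs), list(seed_pairs), 0, 0)
        _record_tp(dataset, seed_pairs, state)
        return Matching(pi), state
    if seed_pairs:
        return _ipa_seeded(dataset, seed_pairs, config, scorer)
    return _ipa_seedless(dataset, config, scorer)


def _ipa_seeded(dataset, seed_pairs, config, scorer):
    m = dataset.depth
    gold = list(seed_pairs)
    state = IPAState(gold, list(seed_pairs), 0, 0)
    while len(gold) < m:
        state.iterations += 1
        scorer.fit(CoMSA.from_pairs(dataset, gold))
        state.model_fits += 1
        proposals: list[tuple[float, int, int]] = []
        gold_a = {a for a, _ in gold}
        for sp, (a_idx, _) in dataset.species_pairs().items():
            if all(a in gold_a for a in a_idx):
                continue
            sa = score_species(scorer, dataset, sp, exclude=gold)
            proposals.extend((g, a, b) for a, b, g in sa.proposed_pairs())
        proposals.sort(key=lambda t: (-t[0], t[1]))
        # forced (1x1) pairs carry infinite confidence and are all promoted;
        # otherwise promote n_increment per iteration
        n_certain = sum(1 for g, _, _ in proposals if np.isinf(g))
        take = max(config.n_increment, n_certain)
        promoted = proposals[: min(take, len(proposals))]
        gold.extend((a, b) for _, a, b in promoted)
        _record_tp(
            dataset,
            gold + [(a, b) for _, a, b in proposals[len(promoted):]],
            state,
        )
    state.gold_pairs = gold
    pi = np.empty(m, dtype=np.int64)
    for a, b in gold:
        pi[a] = b
    return Matching(pi), state


def _ipa_seedless(dataset, config, scorer):
    m = dataset.depth
    rng = np.random.default_rng(config.seed)
    current = dataset.random_matching(rng)
    state = IPAState([], [], 0, 0)
    gold: list[tuple[int, int]] = []
    n = 0
    while len(gold) < m:
        n += 1
        state.iterations = n
        training = (
            CoMSA.from_matching(dataset, current)
            if n == 1
            else CoMSA.from_pairs(dataset, gold)
        )
        scorer.fit(training)
        state.model_fits += 1
        proposals: list[tuple[float, int, int]] = []
        pi = np.empty(m, dtype=np.int64)
        for sp in dataset.species_pairs():
            sa = score_species(scorer, dataset, sp)
            for a, b, g in sa.proposed_pairs():
                proposals.append((g, a, b))
                pi[a] = b
        current = Matching(pi)
        proposals.sort(key=lambda t: (-t[0], t[1]))
        n_certain = sum(1 for g, _, _ in proposals if np.isinf(g))
        take = max(n * config.n_increment, n_certain)
        gold = [(a, b) for _, a, b in proposals[: min(take, m)]]
        _record_tp(dataset, current.pairs(), state)
    state.gold_pairs = gold
    return current, state


def ga_ipa(
    dataset: PairedDataset,
    ga_config: Optional[GAConfig] = None,
    ipa_config: Optional[IPAConfig] = None,
    flavor: str = "knn",
    k: int = 21,
    nets: Optional[tuple] = None,
    return_details: bool = False,
):
    """Full two-stage pipeline: replicated graph alignment, robust-pair
    extraction, then seeded IPA.  Falls back to seedless IPA (with a
    warning) if no pair is robust across replicates."""
    ga_config = ga_config or GAConfig()
    ipa_config = ipa_config or IPAConfig()
    if nets is None:
        net_a = build_network(dataset.msa_a, flavor=flavor, k=k)
        net_b = build_network(dataset.msa_b, flavor=flavor, k=k)
    else:
        net_a, net_b = nets
    results = replicated_anneal(dataset, net_a, net_b, ga_config)
    robust = robust_pairs(results)
    if len(robust) == 0:
        warnings.warn("no robust pairs across GA replicates; running seedless IPA")
        matching, state = ipa_run(dataset, None, ipa_config)
    else:
        matching, state = ipa_run(dataset, robust, ipa_config)
    if return_details:
        return matching, state, robust, results
    return matching
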