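"""Synthetic paired protein families with planted ground truth.

The generator emulates the two evolutionary signals that paralog-pairing
methods exploit, with an independent knob for each:

* **Shared phylogeny** — a pure-birth (Yule) species tree with unit depth is
  drawn, and a fixed number of *copy lineages* (ancient duplicates of the
  ancestral A-B pair) evolve down it.  Every branch of every copy lineage
  carries a random evolutionary-rate multiplier that is shared between the
  A and the B member of the pair (interacting partners co-diverge).  Each
  species then retains a random subset of copies — the same subset in both
  families — and every retained copy diverges further along a short
  species-specific branch.  Rate co-modulation plus the shared
  presence/absence pattern make the Hamming-distance structure of the two
  families mirror each other under the planted pairing; the knob is
  ``rate_cv`` (coefficient of variation of branch rates, 0 = no mirror
  signal beyond topology).

* **Residue coevolution** — ``n_coupled`` designated column pairs (one
  column in A, one in B) co-mutate: when such a pair mutates, with
  probability ``coupling_strength`` both columns jump to a compatible symbol
  pair ``(a, phi(a))`` under a fixed random symbol bijection ``phi``, and
  with the complementary probability both mutate independently.  At
  ``coupling_strength = 0`` coupled columns carry no signal beyond shared
  mutation timing; at 1 their correspondence is deterministic.

A ``tree="star"`` species tree removes all cross-species phylogenetic
signal (all tips hang directly off the root), isolating the coevolution
channel.  The planted within-species matching is returned as ground truth;
family-B rows are shuffled within species so the truth is never the
identity by construction.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np

from .data_model import LabeledMSA, Matching, PairedDataset, Q


@dataclass
class SimConfig:
    """Generator settings.

    ``mutation_rate`` is the expected number of substitutions per column
    over one unit of branch length (the species tree has depth 1).
    Multiplicities are drawn from a geometric distribution shifted to start
    at ``m_min`` and truncated at ``n_copies``, with mean ``m_mean``.
    """

    n_species: int = 50
    n_copies: int = 8
    m_min: int = 2
    m_mean: float = 4.0
    l_a: int = 40
    l_b: int = 40
    q: int = Q
    mutation_rate: float = 1.5
    dup_branch_frac: float = 0.1
    copy_divergence: float = 1.0
    rate_cv: float = 1.0
    n_coupled: int = 10
    coupling_strength: float = 0.5
    tree: str = "yule"  # "yule" | "star"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not 2 <= self.m_min <= self.n_copies:
            raise ValueError("need m_min >= 2 and m_min <= n_copies")
        if not self.m_min <= self.m_mean <= self.n_copies:
            raise ValueError("m_mean must lie in [m_min, n_copies]")
        if self.n_coupled > min(self.l_a, self.l_b):
            raise ValueError("n_coupled cannot exceed min(l_a, l_b)")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not 2 <= self.q <= Q:
            raise ValueError(f"alphabet size must lie in [2, {Q}]")
        if self.tree not in ("yule", "star"):
            raise ValueError("tree must be 'yule' or 'star'")
        if min(self.mutation_rate, self.dup_branch_frac, self.copy_divergence) < 0:
            raise ValueError("rates and branch lengths must be non-negative")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be non-negative")


@dataclass
class SimOutput:
    """A planted dataset plus its provenance (species tree, config, and the
    planted coupled column pairs)."""

    dataset: PairedDataset
    tree_newick: str
    config: SimConfig
    coupled_pairs: list[tuple[int, int]] = field(default_factory=list)


def _species_tree(config: SimConfig) -> dendropy.Tree:
    if config.tree == "star":
        taxa = dendropy.TaxonNamespace([f"sp{i}" for i in range(config.n_species)])
        tree = dendropy.Tree(taxon_namespace=taxa)
        for taxon in taxa:
            child = tree.seed_node.new_child(edge_length=1.0)
            child.taxon = taxon
        return tree
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=_pyrandom.Random(int(config.seed) % 2**31),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i}"
    return tree


class _Evolver:
    """Branch-wise mutation of an (A, B) sequence pair with coupled columns."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        cols_a = rng.permutation(config.l_a)[: config.n_coupled]
        cols_b = rng.permutation(config.l_b)[: config.n_coupled]
        self.coupled = list(zip(cols_a.tolist(), cols_b.tolist()))
        # fixed symbol correspondence phi per coupled column pair
        self.phi = [rng.permutation(config.q) for _ in self.coupled]
        self.free_a = np.setdiff1d(np.arange(config.l_a), cols_a)
        self.free_b = np.setdiff1d(np.arange(config.l_b), cols_b)

    def root_pair(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.rng.integers(self.cfg.q, size=self.cfg.l_a).astype(np.uint8)
        b = self.rng.integers(self.cfg.q, size=self.cfg.l_b).astype(np.uint8)
        for (ia, jb), phi in zip(self.coupled, self.phi):
            b[jb] = phi[a[ia]]
        return a, b

    def branch_rate(self) -> float:
        """Rate multiplier shared by both families along one branch."""
        cv = self.cfg.rate_cv
        if cv == 0:
            return 1.0
        shape = 1.0 / cv**2
        return float(self.rng.gamma(shape, 1.0 / shape))

    def evolve(self, a: np.ndarray, b: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Evolve a pair along one branch of length ``t`` (one shared rate)."""
        if t <= 0:
            return a.copy(), b.copy()
        rng = self.rng
        cfg = self.cfg
        a = a.copy()
        b = b.copy()
        p = 1.0 - np.exp(-cfg.mutation_rate * t * self.branch_rate())
        hit_a = self.free_a[rng.random(self.free_a.size) < p]
        a[hit_a] = rng.integers(cfg.q, size=hit_a.size)
        hit_b = self.free_b[rng.random(self.free_b.size) < p]
        b[hit_b] = rng.integers(cfg.q, size=hit_b.size)
        for (ia, jb), phi in zip(self.coupled, self.phi):
            if rng.random() >= p:
                continue
            if rng.random() < cfg.coupling_strength:
                new = rng.integers(cfg.q)
                a[ia] = new
                b[jb] = phi[new]
            else:
                a[ia] = rng.integers(cfg.q)
                b[jb] = rng.integers(cfg.q)
        return a, b


def _multiplicity(config: SimConfig, rng: np.random.Generator) -> int:
    p = 1.0 / (config.m_mean - config.m_min + 1.0)
    while True:
        m = config.m_min - 1 + int(rng.geometric(p))
        if m <= config.n_copies:
            return m


def simulate(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimOutput:
    """Generate a :class:`PairedDataset` with planted truth (see module
    docstring for the generative model)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tree = _species_tree(config)
    ev = _Evolver(config, rng)
    root_a, root_b = ev.root_pair()
    # ancient duplications: each copy lineage diverges from the family root
    copy_roots = [
        ev.evolve(root_a, root_b, config.copy_divergence)
        for _ in range(config.n_copies)
    ]
    # evolve every copy lineage down the species tree
    state: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    tip_state: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[id(node)] = copy_roots
            continue
        parent = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        evolved = [ev.evolve(a, b, t) for a, b in parent]
        state[id(node)] = evolved
        if node.is_leaf():
            tip_state[node.taxon.label] = evolved
    # per species: retain a random copy subset (shared by both families) and
    # add a short species-specific divergence branch per retained copy
    ids_a, ids_b, species_a, rows_a, rows_b, copy_of = [], [], [], [], [], []
    for s in range(config.n_species):
        label = f"sp{s}"
        m_p = _multiplicity(config, rng)
        kept = np.sort(rng.choice(config.n_copies, size=m_p, replace=False))
        for c in kept:
            a, b = ev.evolve(*tip_state[label][c], config.dup_branch_frac)
            rows_a.append(a)
            rows_b.append(b)
            ids_a.append(f"A_{label}_c{c}")
            ids_b.append(f"B_{label}_c{c}")
            species_a.append(label)
            copy_of.append((label, int(c)))
    # shuffle B rows within each species so truth is not the identity
    order = np.arange(len(rows_b))
    by_species: dict[str, list[int]] = {}
    for idx, sp in enumerate(species_a):
        by_species.setdefault(sp, []).append(idx)
    for sp, idxs in by_species.items():
        idxs = np.asarray(idxs)
        order[idxs] = rng.permutation(idxs)
    codes_a = _pad_alphabet(np.vstack(rows_a), config)
    codes_b = _pad_alphabet(np.vstack(rows_b), config)[order]
    msa_a = LabeledMSA.from_codes(codes_a, ids_a, species_a)
    msa_b = LabeledMSA.from_codes(
        codes_b, [ids_b[i] for i in order], [species_a[i] for i in order]
    )
    position_of_b = np.empty(len(order), dtype=np.int64)
    position_of_b[order] = np.arange(len(order))  # old B row -> new position
    truth = Matching(position_of_b)
    dataset = PairedDataset(msa_a, msa_b, truth=truth)
    return SimOutput(
        dataset, tree.as_string(schema="newick").strip(), config, list(ev.coupled)
    )


def _pad_alphabet(codes: np.ndarray, config: SimConfig) -> np.ndarray:
    """Simulated symbols 0..q-1 already live inside the 21-letter alphabet."""
    return codes.astype(np.uint8)


def subsample_species(
    dataset: PairedDataset, target_m: int, rng: np.random.Generator
) -> PairedDataset:
    """Retain whole species, drawn at random, until the total number of
    pairs reaches ``target_m``; the truth restricts accordingly."""
    sizes = {sp: len(ix) for sp, ix in dataset.msa_a.species_index.items()}
    if target_m < min(sizes.values()):
        raise ValueError("target_m is below the smallest species size")
    if target_m > dataset.depth:
        raise ValueError("target_m exceeds the dataset depth")
    species = list(sizes)
    species = [species[i] for i in rng.permutation(len(species))]
    chosen: set[str] = set()
    total = 0
    for sp in species:
        if total >= target_m:
            break
        chosen.add(sp)
        total += sizes[sp]
    return _restrict(dataset, chosen)


def select_high_multiplicity(dataset: PairedDataset, target_m: int) -> PairedDataset:
    """Greedily take species in decreasing paralog count (stable order on
    ties) until at least ``target_m`` pairs are collected."""
    items = list(dataset.msa_a.species_index.items())
    items.sort(key=lambda kv: -len(kv[1]))  # stable: ties keep input order
    chosen: set[str] = set()
    total = 0
    for sp, idx in items:
        if total >= target_m:
            break
        chosen.add(sp)
        total += len(idx)
    return _restrict(dataset, chosen)


def _restrict(dataset: PairedDataset, species: set[str]) -> PairedDataset:
    keep_a = [i for i, r in enumerate(dataset.msa_a.records) if r.species in species]
    keep_b = [i for i, r in enumerate(dataset.msa_b.records) if r.species in species]
    new_pos_b = {old: new for new, old in enumerate(keep_b)}
    msa_a = LabeledMSA([dataset.msa_a.records[i] for i in keep_a])
    msa_b = LabeledMSA([dataset.msa_b.records[i] for i in keep_b])
    truth = None
    if dataset.truth is not None:
        truth = Matching([new_pos_b[dataset.truth[i]] for i in keep_a])
    return PairedDataset(msa_a, msa_b, truth=truth)
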