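"""Shared fixtures: hand-built datasets with planted structure.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from copair.data_model import (
    ALPHABET,
    LabeledMSA,
    Matching,
    PairedDataset,
    Q,
    decode,
)


def random_msa(
    species_sizes: dict[str, int],
    length: int = 25,
    seed: int = 0,
    family: str = "A",
    dispersed: bool = False,
) -> LabeledMSA:
    """Random MSA with the given species sizes (rows are a.s. distinct).

    With ``dispersed=True``, rows are mutants of a common base sequence at
    subsets of widely varying size, spreading the pairwise Hamming distances
    over a broad range (useful when tests need tie-free neighbor lists).
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(Q, size=length).astype(np.uint8)
    ids, species, rows = [], [], []
    for sp, size in species_sizes.items():
        for c in range(size):
            ids.append(f"{family}_{sp}_{c}")
            species.append(sp)
            if dispersed:
                row = base.copy()
                npos = rng.integers(1, length)
                pos = rng.choice(length, size=npos, replace=False)
                row[pos] = rng.integers(Q, size=npos)
                rows.append(row)
            else:
                rows.append(rng.integers(Q, size=length).astype(np.uint8))
    return LabeledMSA.from_codes(np.vstack(rows), ids, species)


def planted_duplicate_dataset(
    species_sizes: dict[str, int],
    length: int = 25,
    seed: int = 0,
    noise: int = 0,
    dispersed: bool = False,
) -> PairedDataset:
    """Family B is a copy of family A, shuffled within species by a planted
    permutation (the truth); ``noise`` mutates that many positions per B row."""
    rng = np.random.default_rng(seed)
    msa_a = random_msa(species_sizes, length, seed=seed, family="A", dispersed=dispersed)
    m = msa_a.depth
    order = np.arange(m)
    for idx in msa_a.species_index.values():
        idx = np.asarray(idx)
        order[idx] = rng.permutation(idx)
    codes_b = msa_a.codes[order].copy()
    if noise:
        for r in range(m):
            pos = rng.choice(length, size=noise, replace=False)
            codes_b[r, pos] = rng.integers(Q, size=noise)
    ids_b = [f"B_{msa_a.records[i].species}_{i}" for i in order]
    species_b = [msa_a.records[i].species for i in order]
    msa_b = LabeledMSA.from_codes(codes_b, ids_b, species_b)
    position_of = np.empty(m, dtype=np.int64)
    position_of[order] = np.arange(m)
    return PairedDataset(msa_a, msa_b, truth=Matching(position_of))


def enumerate_matchings(dataset: PairedDataset):
    """All within-species bijections (use only when prod(m_s!) is tiny)."""
    groups = list(dataset.species_pairs().values())
    per_species = [
        [list(zip(a_idx, perm)) for perm in itertools.permutations(b_idx)]
        for a_idx, b_idx in groups
    ]
    m = dataset.depth
    for combo in itertools.product(*per_species):
        pi = np.empty(m, dtype=np.int64)
        for block in combo:
            for a, b in block:
                pi[a] = b
        yield Matching(pi)


def naive_ga_cost(matching, net_a, net_b) -> float:
    """Independent cost oracle: explicit loop over A edges and a B edge dict."""
    wb = {}
    for (m, n), w in zip(net_b.edges, net_b.weights):
        wb[(int(m), int(n))] = w
        wb[(int(n), int(m))] = w
    total = 0.0
    for (m, n), w in zip(net_a.edges, net_a.weights):
        img = (matching[int(m)], matching[int(n)])
        if img in wb:
            total -= w * wb[img]
    return total


@pytest.fixture
def small_duplicate_dataset() -> PairedDataset:
    return planted_duplicate_dataset({"sp1": 3, "sp2": 2, "sp3": 2}, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
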