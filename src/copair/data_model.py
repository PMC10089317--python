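"""Core containers for the paralog-pairing problem.

Two aligned protein families A and B are given as labeled MSAs in which every
sequence carries a species identifier, and every species contributes the same
number of sequences to both families.  The object of interest is a
within-species bijection ``pi`` that assigns to each family-A sequence its
putative interaction partner in family B.  This module provides the MSA
containers, aligned-FASTA I/O with species annotations, Hamming distances,
the :class:`Matching` object, and paired-alignment (co-MSA) concatenation.

Conventions
-----------
* The alphabet has 21 symbols: the 20 amino acids plus the gap ``'-'``.  The
  gap is an ordinary symbol: gap-gap is a match, gap-residue a mismatch.
* Hamming distances are raw mismatch counts (no length normalisation);
  distances are only ever compared within one family.
* Sequences are indexed 0-based internally and 1-based in reports.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from scipy.spatial.distance import cdist, pdist, squareform

#: Amino-acid alphabet with the gap as the 21st symbol (always last).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"
Q = len(ALPHABET)

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)

# ASCII -> symbol code lookup (255 marks an invalid character)
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i


class MSAFormatError(ValueError):
    """Raised for malformed alignments (e.g. ragged record lengths)."""


class HeaderParseError(ValueError):
    """Raised when a FASTA header does not yield a species token."""


def encode(residues: str) -> np.ndarray:
    """Encode a residue string into symbol codes (uint8, gap = ``Q - 1``)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = residues[int(np.argmax(codes == 255))]
        raise MSAFormatError(f"invalid symbol {bad!r}; alphabet is {ALPHABET!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its species label."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        encode(self.residues)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.residues)


def hamming_distance(x, y) -> int:
    """Number of mismatching positions between two equal-length sequences.

    The gap counts as an ordinary 21st symbol.  Accepts residue strings or
    encoded arrays.
    """
    if isinstance(x, str):
        x = encode(x)
    if isinstance(y, str):
        y = encode(y)
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return int(np.count_nonzero(x != y))


class LabeledMSA:
    """An aligned MSA of one family whose records carry species labels.

    Parameters
    ----------
    records:
        Ordered sequence records; order is preserved throughout.

    Attributes
    ----------
    codes:
        ``(M, L)`` uint8 matrix of symbol codes.
    species_index:
        Mapping species -> ordered list of record positions; partitions
        ``range(M)``.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise MSAFormatError("empty MSA")
        length = len(records[0].residues)
        for rec in records:
            if len(rec.residues) != length:
                raise MSAFormatError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {length}"
                )
        self.records: list[SequenceRecord] = records
        self.alignment_length: int = length
        self.codes: np.ndarray = np.vstack([encode(r.residues) for r in records])
        index: dict[str, list[int]] = {}
        for pos, rec in enumerate(records):
            index.setdefault(rec.species, []).append(pos)
        self.species_index: dict[str, list[int]] = index
        singletons = [sp for sp, idx in index.items() if len(idx) == 1]
        if singletons:
            warnings.warn(
                f"{len(singletons)} species have a single sequence; pairing "
                f"is trivial there (e.g. {singletons[0]!r})",
                stacklevel=2,
            )

    # -- basic accessors -------------------------------------------------
    @property
    def depth(self) -> int:
        """Number of sequences M."""
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    @property
    def mean_multiplicity(self) -> float:
        """Average number of paralogs per species, M/N."""
        return self.depth / self.n_species

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def species_of(self) -> np.ndarray:
        """Integer species label per record (order of first appearance)."""
        seen: dict[str, int] = {}
        out = np.empty(self.depth, dtype=np.int64)
        for pos, rec in enumerate(self.records):
            out[pos] = seen.setdefault(rec.species, len(seen))
        return out

    def __len__(self) -> int:
        return self.depth

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabeledMSA) and self.records == other.records

    @classmethod
    def from_codes(
        cls, codes: np.ndarray, ids: Sequence[str], species: Sequence[str]
    ) -> "LabeledMSA":
        records = [
            SequenceRecord(i, s, decode(row))
            for i, s, row in zip(ids, species, codes)
        ]
        return cls(records)


def _species_from_header(header: str, species_pattern: str, path) -> tuple[str, str]:
    """Split a FASTA header into (id, species) under the given rule.

    ``species_pattern`` is either a single delimiter character (the species is
    the token after the last delimiter) or a regular expression with a named
    group ``species`` (or, failing that, group 1).
    """
    if len(species_pattern) == 1:
        seq_id, sep, species = header.rpartition(species_pattern)
        if not sep or not species or not seq_id:
            raise HeaderParseError(
                f"header {header!r} in {path} has no species token under "
                f"delimiter {species_pattern!r}"
            )
        return seq_id, species
    m = re.search(species_pattern, header)
    if m is None:
        raise HeaderParseError(
            f"header {header!r} in {path} does not match pattern "
            f"{species_pattern!r}"
        )
    species = m.groupdict().get("species") or m.group(1)
    if not species:
        raise HeaderParseError(f"empty species token in header {header!r}")
    return header, species


def read_labeled_msa(path, species_pattern: str = "|") -> LabeledMSA:
    """Read an aligned FASTA file whose headers carry species tokens.

    The default header dialect is ``id|species``.  Any single-character
    ``species_pattern`` is treated as a delimiter; longer patterns are
    regular expressions (named group ``species`` or group 1).
    """
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        header = bio.description if bio.description else bio.id
        seq_id, species = _species_from_header(header, species_pattern, path)
        records.append(SequenceRecord(seq_id, species, str(bio.seq).upper()))
    return LabeledMSA(records)


def write_labeled_msa(msa: LabeledMSA, path, delimiter: str = "|") -> None:
    """Write an aligned FASTA with canonical ``id|species`` headers."""
    bios = [
        _BioSeqRecord(Seq(r.residues), id=f"{r.id}{delimiter}{r.species}", description="")
        for r in msa.records
    ]
    SeqIO.write(bios, str(path), "fasta-2line")


def pairwise_hamming(msa_or_codes) -> np.ndarray:
    """All-pairs Hamming distance matrix (raw mismatch counts, int64)."""
    codes = msa_or_codes.codes if isinstance(msa_or_codes, LabeledMSA) else np.asarray(msa_or_codes)
    length = codes.shape[1]
    frac = squareform(pdist(codes, metric="hamming"))
    return np.rint(frac * length).astype(np.int64)


class Matching:
    """A within-species bijection pi over ``{0..M-1}`` mapping A to B indices."""

    def __init__(self, pi: Iterable[int]):
        arr = np.array(list(pi) if not isinstance(pi, np.ndarray) else pi, dtype=np.int64)
        m = arr.size
        if m == 0:
            raise ValueError("empty matching")
        if not np.array_equal(np.sort(arr), np.arange(m)):
            raise ValueError("pi is not a bijection on {0..M-1}")
        self.pi = arr
        self.pi.setflags(write=False)

    @property
    def m(self) -> int:
        return self.pi.size

    def __len__(self) -> int:
        return self.m

    def __getitem__(self, i: int) -> int:
        return int(self.pi[i])

    def __eq__(self, other) -> bool:
        return isinstance(other, Matching) and np.array_equal(self.pi, other.pi)

    def __hash__(self):
        return hash(self.pi.tobytes())

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, int(b)) for i, b in enumerate(self.pi)]

    def inverse(self) -> "Matching":
        inv = np.empty_like(self.pi)
        inv[self.pi] = np.arange(self.m)
        return Matching(inv)

    @classmethod
    def identity(cls, m: int) -> "Matching":
        return cls(np.arange(m))

    def validate_species(self, dataset: "PairedDataset") -> None:
        """Raise if any pair joins sequences of different species."""
        spa = dataset.msa_a.species
        spb = dataset.msa_b.species
        for i, b in enumerate(self.pi):
            if spa[i] != spb[b]:
                raise ValueError(
                    f"pair ({i}, {int(b)}) joins species {spa[i]!r} and {spb[b]!r}"
                )

    def to_frame(self, dataset: "PairedDataset") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_a": [dataset.msa_a.records[i].id for i in range(self.m)],
                "id_b": [dataset.msa_b.records[b].id for b in self.pi],
                "species": [dataset.msa_a.records[i].species for i in range(self.m)],
            }
        )

    def write_tsv(self, path, dataset: "PairedDataset") -> None:
        self.to_frame(dataset).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, dataset: "PairedDataset") -> "Matching":
        """Load a pairing table (columns ``id_a``, ``id_b``) against a dataset."""
        df = pd.read_csv(path, sep="\t")
        pos_a = {r.id: i for i, r in enumerate(dataset.msa_a.records)}
        pos_b = {r.id: i for i, r in enumerate(dataset.msa_b.records)}
        pi = np.empty(dataset.depth, dtype=np.int64)
        for id_a, id_b in zip(df["id_a"], df["id_b"]):
            pi[pos_a[str(id_a)]] = pos_b[str(id_b)]
        return cls(pi)


@dataclass
class PairedDataset:
    """Two labeled MSAs of equal depth over the same species partition."""

    msa_a: LabeledMSA
    msa_b: LabeledMSA
    truth: Optional[Matching] = None

    def __post_init__(self) -> None:
        if self.msa_a.depth != self.msa_b.depth:
            raise ValueError(
                f"depth mismatch: {self.msa_a.depth} vs {self.msa_b.depth}"
            )
        counts_a = {sp: len(ix) for sp, ix in self.msa_a.species_index.items()}
        counts_b = {sp: len(ix) for sp, ix in self.msa_b.species_index.items()}
        if counts_a != counts_b:
            raise ValueError(
                "species partitions differ between families "
                f"(A only: {set(counts_a) - set(counts_b)}; "
                f"B only: {set(counts_b) - set(counts_a)}; "
                "or unequal per-species counts)"
            )
        if self.truth is not None:
            if self.truth.m != self.depth:
                raise ValueError("truth matching size does not match dataset depth")
            self.truth.validate_species(self)

    @property
    def depth(self) -> int:
        return self.msa_a.depth

    @property
    def n_species(self) -> int:
        return self.msa_a.n_species

    @property
    def mean_multiplicity(self) -> float:
        return self.msa_a.mean_multiplicity

    def species_pairs(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-species (A indices, B indices), in record order."""
        return {
            sp: (
                np.asarray(self.msa_a.species_index[sp], dtype=np.int64),
                np.asarray(self.msa_b.species_index[sp], dtype=np.int64),
            )
            for sp in self.msa_a.species_index
        }

    def random_matching(self, rng: np.random.Generator) -> Matching:
        """Uniform random within-species bijection."""
        pi = np.empty(self.depth, dtype=np.int64)
        for a_idx, b_idx in self.species_pairs().values():
            pi[a_idx] = rng.permutation(b_idx)
        return Matching(pi)


class CoMSA:
    """A paired alignment: each row concatenates one A and one B sequence
    from the same species."""

    def __init__(
        self,
        codes: np.ndarray,
        l_a: int,
        ids_a: Sequence[str],
        ids_b: Sequence[str],
        species: Sequence[str],
        index_pairs: Optional[Sequence[tuple[int, int]]] = None,
    ):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or not (0 < l_a < codes.shape[1]):
            raise ValueError("codes must be 2-D with 0 < l_a < total length")
        if not (len(ids_a) == len(ids_b) == len(species) == codes.shape[0]):
            raise ValueError("metadata lengths must equal the number of rows")
        self.codes = codes
        self.l_a = int(l_a)
        self.l_b = int(codes.shape[1] - l_a)
        self.ids_a = list(ids_a)
        self.ids_b = list(ids_b)
        self.species = list(species)
        self.index_pairs = list(index_pairs) if index_pairs is not None else None

    @property
    def depth(self) -> int:
        return self.codes.shape[0]

    @property
    def alignment_length(self) -> int:
        return self.codes.shape[1]

    @property
    def pairs(self) -> list[tuple[SequenceRecord, SequenceRecord]]:
        out = []
        for r in range(self.depth):
            a = SequenceRecord(self.ids_a[r], self.species[r], decode(self.codes[r, : self.l_a]))
            b = SequenceRecord(self.ids_b[r], self.species[r], decode(self.codes[r, self.l_a :]))
            out.append((a, b))
        return out

    @classmethod
    def from_pairs(
        cls, dataset: PairedDataset, index_pairs: Sequence[tuple[int, int]]
    ) -> "CoMSA":
        """Build a (possibly partial) co-MSA from (A-index, B-index) pairs."""
        ia = np.asarray([p[0] for p in index_pairs], dtype=np.int64)
        ib = np.asarray([p[1] for p in index_pairs], dtype=np.int64)
        if ia.size == 0:
            raise ValueError("empty pair list")
        spa = dataset.msa_a.species
        spb = dataset.msa_b.species
        for a, b in zip(ia, ib):
            if spa[a] != spb[b]:
                raise ValueError(
                    f"pair ({int(a)}, {int(b)}) joins species {spa[a]!r} and {spb[b]!r}"
                )
        codes = np.hstack([dataset.msa_a.codes[ia], dataset.msa_b.codes[ib]])
        return cls(
            codes,
            dataset.msa_a.alignment_length,
            [dataset.msa_a.records[i].id for i in ia],
            [dataset.msa_b.records[i].id for i in ib],
            [spa[i] for i in ia],
            index_pairs=list(zip(ia.tolist(), ib.tolist())),
        )

    @classmethod
    def from_matching(cls, dataset: PairedDataset, matching: Matching) -> "CoMSA":
        return cls.from_pairs(dataset, matching.pairs())

    def split(self) -> tuple[LabeledMSA, LabeledMSA]:
        """Undo the concatenation, returning the two family MSAs row-aligned."""
        msa_a = LabeledMSA.from_codes(self.codes[:, : self.l_a], self.ids_a, self.species)
        msa_b = LabeledMSA.from_codes(self.codes[:, self.l_a :], self.ids_b, self.species)
        return msa_a, msa_b

    def write_fasta(self, path) -> None:
        bios = [
            _BioSeqRecord(
                Seq(decode(self.codes[r])),
                id=f"{self.ids_a[r]}|{self.ids_b[r]}|{self.species[r]}",
                description="",
            )
            for r in range(self.depth)
        ]
        SeqIO.write(bios, str(path), "fasta-2line")


def concatenate(matching: Matching, dataset: PairedDataset) -> CoMSA:
    """Concatenate each A sequence with its matched B partner (row m of the
    output is ``a_m ++ b_pi(m)``)."""
    return CoMSA.from_matching(dataset, matching)
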