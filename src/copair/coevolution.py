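"""Coevolution models scoring candidate A-B pairs from a paired alignment.

Two model families are provided, both fit on a (weighted) co-MSA:

* **mean-field DCA** — a pairwise maximum-entropy (Potts) model inferred by
  the standard mean-field route: pseudocount-regularised weighted one- and
  two-site frequencies, a connected-correlation matrix with one reference
  symbol (the gap, last in the alphabet) removed per site, and couplings
  ``J = -(C^-1)``.  Only the inter-family coupling blocks are kept: in
  within-species partner ranking the intra-family terms cancel, since every
  A sequence is paired with exactly one B sequence.  The statistical energy
  of a candidate pair is ``E(a, b) = -sum_{i,j} J(i, j, a_i, b_j)`` (lower
  is better).

* **pointwise mutual information (PMI)** — ``pmi(i, j, a, b) =
  log[f_ij(a,b) / (f_i(a) f_j(b))]`` (natural log) on the same regularised
  weighted frequencies, inter-family column pairs only.  The pair score is
  the summed PMI over all column pairs (higher is better).

Sequence reweighting follows the usual DCA preprocessing: each row's weight
is the inverse of the number of rows within a fractional identity threshold
of it (default 0.8), itself included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import CoMSA, Q, encode


class CouplingInferenceError(RuntimeError):
    """Raised when model inference fails numerically (e.g. a singular
    correlation matrix); raising the pseudocount usually fixes it."""


@dataclass
class WeightedCoMSA:
    """A co-MSA with per-row weights in (0, 1] and their sum."""

    comsa: CoMSA
    sequence_weights: np.ndarray
    effective_depth: float


@dataclass
class CouplingModel:
    """Inter-family coupling (DCA) or PMI tables over the co-MSA columns.

    ``tensor`` has shape ``(L_A, L_B, q, q)``: the couplings ``J`` for DCA
    (gap row/column zero by the reference-symbol gauge) or the PMI table.
    """

    model_kind: str  # "dca" or "mi"
    tensor: np.ndarray
    l_a: int
    l_b: int
    pseudocount: float
    source_depth: float

    def __post_init__(self) -> None:
        if self.model_kind not in ("dca", "mi"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not np.isfinite(self.tensor).all():
            raise CouplingInferenceError("non-finite model entries")

    def score_matrix(self, a_codes: np.ndarray, b_codes: np.ndarray) -> np.ndarray:
        """Larger-is-better scores for all (A row, B row) combinations.

        For DCA this is the negated statistical energy ``sum J``; for MI it
        is the summed PMI.
        """
        a_codes = np.atleast_2d(np.asarray(a_codes))
        b_codes = np.atleast_2d(np.asarray(b_codes))
        if a_codes.shape[1] != self.l_a or b_codes.shape[1] != self.l_b:
            raise ValueError("sequence lengths do not match the model dimensions")
        n_a = a_codes.shape[0]
        gathered = np.zeros((n_a, self.l_b, self.tensor.shape[3]))
        for i in range(self.l_a):
            gathered += self.tensor[i, :, a_codes[:, i], :]
        scores = np.zeros((n_a, b_codes.shape[0]))
        for j in range(self.l_b):
            scores += gathered[:, j, b_codes[:, j]]
        return scores

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            model_kind=self.model_kind,
            tensor=self.tensor,
            l_a=self.l_a,
            l_b=self.l_b,
            pseudocount=self.pseudocount,
            source_depth=self.source_depth,
        )

    @classmethod
    def load(cls, path) -> "CouplingModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                model_kind=str(z["model_kind"]),
                tensor=z["tensor"],
                l_a=int(z["l_a"]),
                l_b=int(z["l_b"]),
                pseudocount=float(z["pseudocount"]),
                source_depth=float(z["source_depth"]),
            )


def sequence_weights(comsa: CoMSA, identity_threshold: float = 0.8) -> WeightedCoMSA:
    """Down-weight redundant rows of a co-MSA.

    Row r's weight is ``1 / |{rows within (1 - identity_threshold) normalised
    Hamming distance of r, r included}|``.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    if comsa.depth == 0:
        raise ValueError("empty co-MSA")
    if comsa.depth == 1:
        w = np.ones(1)
    else:
        frac = squareform(pdist(comsa.codes, metric="hamming"))
        neighbors = (frac <= (1.0 - identity_threshold) + 1e-12).sum(axis=1)
        w = 1.0 / neighbors
    return WeightedCoMSA(comsa, w, float(w.sum()))


def _weighted_frequencies(wcomsa: WeightedCoMSA, q: int = Q):
    """Weighted one-hot encoding and single-site frequencies."""
    codes = wcomsa.comsa.codes
    m, l_tot = codes.shape
    w = wcomsa.sequence_weights / wcomsa.effective_depth
    one_hot = np.zeros((m, l_tot, q))
    rows = np.repeat(np.arange(m), l_tot)
    cols = np.tile(np.arange(l_tot), m)
    one_hot[rows, cols, codes.ravel()] = 1.0
    f_i = np.einsum("m,mia->ia", w, one_hot)
    return one_hot, w, f_i


def fit_pmi(wcomsa: WeightedCoMSA, pseudocount: float = 0.5) -> CouplingModel:
    """Pointwise-mutual-information tables for inter-family column pairs."""
    if not 0.0 < pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in (0, 1]")
    lam = pseudocount
    l_a = wcomsa.comsa.l_a
    one_hot, w, f_i = _weighted_frequencies(wcomsa)
    xa = one_hot[:, :l_a, :]
    xb = one_hot[:, l_a:, :]
    f_ij = np.einsum("m,mia,mjb->ijab", w, xa, xb, optimize=True)
    f_ij = (1.0 - lam) * f_ij + lam / Q**2
    fa = (1.0 - lam) * f_i[:l_a] + lam / Q
    fb = (1.0 - lam) * f_i[l_a:] + lam / Q
    pmi = np.log(f_ij) - np.log(fa[:, None, :, None]) - np.log(fb[None, :, None, :])
    return CouplingModel(
        "mi", pmi, l_a, wcomsa.comsa.l_b, lam, wcomsa.effective_depth
    )


def fit_dca(wcomsa: WeightedCoMSA, pseudocount: float = 0.5) -> CouplingModel:
    """Mean-field DCA restricted to inter-family coupling blocks."""
    if not 0.0 < pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in (0, 1]")
    lam = pseudocount
    l_a = wcomsa.comsa.l_a
    l_b = wcomsa.comsa.l_b
    l_tot = l_a + l_b
    qr = Q - 1  # reference symbol (gap, last) removed per site
    one_hot, w, f_i = _weighted_frequencies(wcomsa)
    x = one_hot[:, :, :qr].reshape(one_hot.shape[0], l_tot * qr)
    # raw weighted pair frequencies over the reduced alphabet; the diagonal
    # site blocks come out as diag(f_i) automatically
    f_pair = (x * w[:, None]).T @ x
    f_pair = f_pair.reshape(l_tot, qr, l_tot, qr)
    ft_pair = (1.0 - lam) * f_pair + lam / Q**2
    site = np.arange(l_tot)
    ft_pair[site, :, site, :] = (1.0 - lam) * f_pair[site, :, site, :] + (
        lam / Q
    ) * np.eye(qr)
    ft_i = (1.0 - lam) * f_i[:, :qr] + lam / Q
    corr = ft_pair - np.einsum("ia,jb->iajb", ft_i, ft_i)
    corr = corr.reshape(l_tot * qr, l_tot * qr)
    try:
        j_full = -np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs lam ~ 0
        raise CouplingInferenceError(
            "singular correlation matrix; raise the pseudocount"
        ) from exc
    j_full = j_full.reshape(l_tot, qr, l_tot, qr)
    tensor = np.zeros((l_a, l_b, Q, Q))
    tensor[:, :, :qr, :qr] = np.transpose(j_full[:l_a, :, l_a:, :], (0, 2, 1, 3))
    return CouplingModel("dca", tensor, l_a, l_b, lam, wcomsa.effective_depth)


def pair_score(model: CouplingModel, a, b) -> float:
    """Score one candidate A-B pair in the model's native orientation.

    DCA: statistical energy ``E = -sum J`` (lower is better).
    MI: summed PMI (higher is better).
    """
    if isinstance(a, str):
        a = encode(a)
    if isinstance(b, str):
        b = encode(b)
    s = float(model.score_matrix(a, b)[0, 0])
    return -s if model.model_kind == "dca" else s


def coupling_norms(model: CouplingModel) -> np.ndarray:
    """Frobenius norm of each inter-family (i, j) block; used to rank
    column pairs by interaction signal."""
    return np.sqrt((model.tensor**2).sum(axis=(2, 3)))
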