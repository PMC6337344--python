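"""Sequence reweighting and the effective number of sequences (Meff).

Sequences in an alignment are not independent samples: phylogeny produces
clusters of near-duplicates.  Each sequence n is therefore down-weighted by
the size m_n of its similarity neighborhood — the number of sequences
(including itself) sharing at least r*L identical amino acids with it — via
w(n) = 1/m_n.  Meff, the sum of the weights, measures the alignment's
information content and is the quantity used to stratify families into
small (<500), medium (500-1000) and large (>1000) groups.

Identity counts only positions where both sequences carry the same non-gap
amino acid; a gap aligned with a gap is not an identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import GAP_INDEX
from .msa_io import MSA

#: auto-mode cutoff constants: r = clip(RHO / mean pairwise identity, R_MIN, R_MAX)
AUTO_RHO = 0.32
AUTO_R_MIN = 0.5
AUTO_R_MAX = 0.9
DEFAULT_FIXED_R = 0.8


@dataclass
class WeightingResult:
    """Per-sequence weights w(n) = 1/m_n and their sum Meff."""

    weights: np.ndarray
    neighbor_counts: np.ndarray
    r: float

    @property
    def meff(self) -> float:
        return float(self.weights.sum())

    def to_tsv(self, path, ids=None) -> None:
        n = len(self.weights)
        ids = ids if ids is not None else [f"seq{i + 1}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("id\tm\tweight\n")
            for rid, m, w in zip(ids, self.neighbor_counts, self.weights):
                fh.write(f"{rid}\t{int(m)}\t{w:.10g}\n")


def identity_counts(msa: MSA) -> np.ndarray:
    """(N, N) integer matrix of matched non-gap positions between sequences."""
    idx = msa.to_indices()
    N, L = idx.shape
    # One-hot over the 20 amino acids (gap channel excluded); a single BLAS
    # product then yields all pairwise match counts.  Counts are <= L << 2^24
    # so float32 accumulation is exact.
    onehot = np.zeros((N, L * 20), dtype=np.float32)
    rows = np.repeat(np.arange(N), L)
    pos = np.tile(np.arange(L), N)
    aa = idx.ravel()
    keep = aa != GAP_INDEX
    onehot[rows[keep], pos[keep] * 20 + aa[keep]] = 1.0
    counts = onehot @ onehot.T
    return np.rint(counts).astype(np.int64)


def pairwise_identity(msa: MSA) -> np.ndarray:
    """Fraction of positions with matching non-gap amino acids, per pair.

    The diagonal is set to 1.0 by convention (a sequence is always in its
    own neighborhood), regardless of its gap content.
    """
    frac = identity_counts(msa) / msa.L
    np.fill_diagonal(frac, 1.0)
    return frac


def similarity_cutoff(
    msa: MSA,
    mode: str = "fixed",
    fixed_r: float = DEFAULT_FIXED_R,
    rho: float = AUTO_RHO,
    r_min: float = AUTO_R_MIN,
    r_max: float = AUTO_R_MAX,
) -> float:
    """Identity cutoff r used to define similarity neighborhoods.

    ``fixed`` returns ``fixed_r``.  ``auto`` makes r inversely proportional
    to the mean off-diagonal pairwise identity (rho / mean identity),
    clipped to [r_min, r_max]; with a single sequence there are no pairs and
    the fixed default is returned.
    """
    if mode == "fixed":
        if not 0 < fixed_r <= 1:
            raise ValueError(f"fixed_r must be in (0, 1], got {fixed_r}")
        return float(fixed_r)
    if mode != "auto":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    if msa.N == 1:
        return float(fixed_r)
    ident = pairwise_identity(msa)
    off = ident[~np.eye(msa.N, dtype=bool)]
    mean_id = float(off.mean())
    if mean_id <= 0:
        return float(r_max)
    return float(np.clip(rho / mean_id, r_min, r_max))


def sequence_weights(msa: MSA, r: float) -> WeightingResult:
    """Weights w(n) = 1/m_n with m_n = #{sequences at identity >= r}.

    The comparison is "at least r*L identical amino acids"; self always
    counts, so 0 < w(n) <= 1 and 1 <= Meff <= N.
    """
    if not 0 < r <= 1:
        raise ValueError(f"cutoff r must be in (0, 1], got {r}")
    counts = identity_counts(msa)
    # small slack guards against float representation of r*L (e.g. 0.8*10)
    neighbors = counts >= (r * msa.L - 1e-9)
    np.fill_diagonal(neighbors, True)
    m = neighbors.sum(axis=1).astype(np.int64)
    return WeightingResult(weights=1.0 / m, neighbor_counts=m, r=float(r))
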