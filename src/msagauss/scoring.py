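"""From the coupling matrix to ranked contact predictions.

Each inter-position s x s block J(i,j) of the precision matrix is reduced
to a scalar score: the block is double-centered (row means and column
means subtracted, grand mean added back — the zero-sum gauge, which makes
the score invariant to additive row/column shifts of the block) and the
score is the sum of its squared entries (the squared Frobenius norm; any
monotone transform leaves rankings unchanged).  The L x L score matrix is
then average-product corrected (APC) to suppress positional background and
phylogenetic signal, and pairs with j - i > min_separation are ranked in
decreasing corrected score.

Positions are 1-based in all reported pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def double_center(block: np.ndarray) -> np.ndarray:
    """Zero-sum gauge: subtract row and column means, add the grand mean."""
    block = np.asarray(block, dtype=float)
    return (
        block
        - block.mean(axis=1, keepdims=True)
        - block.mean(axis=0, keepdims=True)
        + block.mean()
    )


def pair_score(block: np.ndarray) -> float:
    """Gauge-corrected squared Frobenius norm of one coupling block.

    For scalar (s=1) couplings the zero-sum gauge is degenerate — double
    centering annihilates a 1x1 block entirely — so the score is the plain
    squared coupling, which carries the same affine-invariance property.
    """
    block = np.asarray(block, dtype=float)
    if block.shape == (1, 1):
        return float(block[0, 0] ** 2)
    c = double_center(block)
    return float(np.sum(c * c))


def score_matrix(J: np.ndarray, L: int, s: int) -> np.ndarray:
    """L x L matrix of pair scores from the L*s x L*s coupling matrix.

    The diagonal is zero: a position is not a pair with itself and its
    self-coupling block carries no contact information.
    """
    if J.shape != (L * s, L * s):
        raise ValueError(f"coupling matrix shape {J.shape} != ({L * s}, {L * s})")
    if s == 1:
        P = J * J  # scalar couplings: the gauge correction is degenerate
    else:
        blocks = J.reshape(L, s, L, s).transpose(0, 2, 1, 3)  # (L, L, s, s)
        centered = (
            blocks
            - blocks.mean(axis=3, keepdims=True)
            - blocks.mean(axis=2, keepdims=True)
            + blocks.mean(axis=(2, 3), keepdims=True)
        )
        P = np.sum(centered * centered, axis=(2, 3))
    np.fill_diagonal(P, 0.0)
    return 0.5 * (P + P.T)


def apc_correct(P: np.ndarray, mask_near_diagonal: int | None = None) -> np.ndarray:
    """Average-product correction: P(i,j) - rowmean_i * rowmean_j / grandmean.

    Evaluated literally over the full matrix.  ``mask_near_diagonal``, when
    set to an integer d, excludes entries with |i - j| <= d from the row and
    total sums (default: no masking).  An all-zero input is returned
    unchanged with a warning, since the correction is then undefined.
    """
    P = np.asarray(P, dtype=float)
    if P.shape[0] != P.shape[1]:
        raise ValueError("score matrix must be square")
    if mask_near_diagonal is not None:
        i, j = np.indices(P.shape)
        w = (np.abs(i - j) > mask_near_diagonal).astype(float)
        masked = P * w
        rowsum = masked.sum(axis=1)
        colsum = masked.sum(axis=0)
        total = masked.sum()
    else:
        rowsum = P.sum(axis=1)
        colsum = P.sum(axis=0)
        total = P.sum()
    if total == 0:
        warnings.warn("score matrix sums to zero; APC correction skipped")
        return P.copy()
    return P - np.outer(rowsum, colsum) / total


@dataclass
class ContactPrediction:
    """Ranked predicted contacts: (i, j, apc_score, raw_score), 1-based, i<j."""

    pairs: list[tuple[int, int]]
    apc_scores: list[float]
    raw_scores: list[float] = field(default_factory=list)
    min_separation: int = 4

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        raw = self.raw_scores or [float("nan")] * len(self.pairs)
        with open(path, "w") as fh:
            fh.write("rank\ti\tj\traw_score\tapc_score\n")
            for rank, ((i, j), a, r) in enumerate(
                zip(self.pairs, self.apc_scores, raw), start=1
            ):
                fh.write(f"{rank}\t{i}\t{j}\t{r:.10g}\t{a:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactPrediction":
        pairs, apc, raw = [], [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = {name: k for k, name in enumerate(header)}
            for line in fh:
                f = line.split("\t")
                pairs.append((int(f[col["i"]]), int(f[col["j"]])))
                apc.append(float(f[col["apc_score"]]))
                raw.append(float(f[col["raw_score"]]))
        return cls(pairs=pairs, apc_scores=apc, raw_scores=raw)


def rank_contacts(
    p_apc: np.ndarray,
    p_raw: np.ndarray | None = None,
    min_separation: int = 4,
    top_k: int = 200,
) -> ContactPrediction:
    """Rank pairs (i, j) with j - i > min_separation by decreasing score.

    Ties break lexicographically on (i, j) for determinism.  At most
    ``top_k`` pairs are returned; if fewer are eligible, all are.
    """
    L = p_apc.shape[0]
    entries = []
    for i in range(L):
        for j in range(i + min_separation + 1, L):
            entries.append((-p_apc[i, j], i + 1, j + 1))
    if not entries:
        warnings.warn(
            f"no eligible pairs: L={L} with min_separation={min_separation}"
        )
        return ContactPrediction(pairs=[], apc_scores=[], raw_scores=[],
                                 min_separation=min_separation)
    entries.sort()
    entries = entries[:top_k]
    pairs = [(i, j) for _, i, j in entries]
    apc = [-neg for neg, _, _ in entries]
    raw = (
        [float(p_raw[i - 1, j - 1]) for i, j in pairs]
        if p_raw is not None
        else []
    )
    return ContactPrediction(
        pairs=pairs, apc_scores=apc, raw_scores=raw, min_separation=min_separation
    )
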