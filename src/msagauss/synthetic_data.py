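"""Seeded synthetic alignments with planted covarying column pairs.

The generator emulates the features of a real protein family alignment
that the model exercises — background residue composition, directly
coupled column pairs, gaps, and duplicated sequences that stress the
reweighting — without any phylogenetic simulation.  Coupling is pairwise
and explicit: for a planted pair (i, j), with probability ``coupling`` the
two residues are drawn jointly from a pair table (by default perfectly
matched types, P(a, a) = background(a)), otherwise independently from the
background.  A chained preset (i-j and j-k planted, i-k not) produces an
indirect correlation between i and k, the situation the precision matrix
exists to discount.

All draws come from a single numpy Generator stream seeded from the spec,
so the output is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, GAP, GAP_INDEX
from .msa_io import MSA

DEFAULT_L = 60
DEFAULT_N = 2000
DEFAULT_N_PAIRS = 8
DEFAULT_COUPLING = 0.8
DEFAULT_GAP_RATE = 0.05


def default_planted_pairs(
    L: int = DEFAULT_L, n_pairs: int = DEFAULT_N_PAIRS, min_separation: int = 4
) -> list[tuple[int, int]]:
    """Evenly spaced disjoint pairs (i, i + min_separation + 1), 1-based."""
    span = min_separation + 1
    pairs = []
    i = 1
    while len(pairs) < n_pairs and i + span <= L:
        pairs.append((i, i + span))
        i += 2 * span - 3
    if len(pairs) < n_pairs:
        raise ValueError(f"cannot place {n_pairs} disjoint pairs in L={L}")
    return pairs


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic alignment.

    ``planted_pairs`` must be disjoint position pairs with j - i > 4;
    ``chained_triples`` plants i-j and j-k couplings that share position j
    (the i-k correlation is then purely indirect).  ``duplicate_rate`` is
    the fraction of emitted rows that are exact copies of earlier rows.
    """

    L: int = DEFAULT_L
    N: int = DEFAULT_N
    planted_pairs: list[tuple[int, int]] | None = None
    chained_triples: list[tuple[int, int, int]] = field(default_factory=list)
    coupling: float = DEFAULT_COUPLING
    background: np.ndarray | None = None
    gap_rate: float = DEFAULT_GAP_RATE
    duplicate_rate: float = 0.0
    seed: int = 0
    min_separation: int = 4

    def __post_init__(self) -> None:
        if self.planted_pairs is None and not self.chained_triples:
            self.planted_pairs = default_planted_pairs(self.L)
        self.planted_pairs = list(self.planted_pairs or [])
        if self.background is None:
            self.background = np.full(20, 0.05)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 20-simplex frequency vector")
        for rate, name in [
            (self.coupling, "coupling"),
            (self.gap_rate, "gap_rate"),
            (self.duplicate_rate, "duplicate_rate"),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.duplicate_rate >= 1:
            raise ValueError("duplicate_rate must leave at least one unique row")
        used: set[int] = set()
        for i, j in self.planted_pairs:
            if j - i <= self.min_separation:
                raise ValueError(f"planted pair ({i},{j}) violates j-i>{self.min_separation}")
            if not (1 <= i < j <= self.L):
                raise ValueError(f"planted pair ({i},{j}) outside 1..{self.L}")
            if i in used or j in used:
                raise ValueError(f"planted pair ({i},{j}) overlaps another pair")
            used.update((i, j))
        for i, j, k in self.chained_triples:
            if not (1 <= i < j < k <= self.L):
                raise ValueError(f"chained triple ({i},{j},{k}) must satisfy 1<=i<j<k<=L")
            if j - i <= self.min_separation or k - j <= self.min_separation:
                raise ValueError(f"chained triple ({i},{j},{k}) spacing too small")
            if used & {i, j, k}:
                raise ValueError(f"chained triple ({i},{j},{k}) overlaps planted pairs")
            used.update((i, j, k))

    @property
    def truth_pairs(self) -> list[tuple[int, int]]:
        """All directly coupled pairs (planted pairs + the two direct legs
        of each chained triple)."""
        pairs = list(self.planted_pairs)
        for i, j, k in self.chained_triples:
            pairs.extend([(i, j), (j, k)])
        return pairs


@dataclass
class SyntheticTruth:
    """Ground truth for one generated alignment."""

    planted_pairs: list[tuple[int, int]]
    chained_triples: list[tuple[int, int, int]]
    spec: SyntheticSpec

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tl\n")
            for i, j in sorted(self.planted_pairs):
                fh.write(f"{i}\t{j}\n")


def chained_pairs_spec(
    L: int = DEFAULT_L,
    N: int = DEFAULT_N,
    coupling: float = DEFAULT_COUPLING,
    gap_rate: float = DEFAULT_GAP_RATE,
    seed: int = 0,
) -> SyntheticSpec:
    """Preset with a single chained triple (direct i-j, j-k; indirect i-k)."""
    third = max(6, L // 3)
    i, j, k = 1, 1 + third, 1 + 2 * third
    return SyntheticSpec(
        L=L,
        N=N,
        planted_pairs=[],
        chained_triples=[(i, j, k)],
        coupling=coupling,
        gap_rate=gap_rate,
        seed=seed,
    )


def generate_msa(spec: SyntheticSpec) -> tuple[MSA, SyntheticTruth]:
    """Draw one alignment from the spec; bitwise reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    n_unique = max(1, int(round(spec.N * (1 - spec.duplicate_rate))))
    idx = rng.choice(20, size=(n_unique, spec.L), p=spec.background)

    def couple(src_col: int, dst_col: int) -> None:
        # matched-type pair table: with prob `coupling` the dst residue is
        # forced equal to the src residue, so P(a, a) = background(a)
        mask = rng.random(n_unique) < spec.coupling
        idx[mask, dst_col - 1] = idx[mask, src_col - 1]

    for i, j in spec.planted_pairs:
        couple(i, j)
    for i, j, k in spec.chained_triples:
        couple(j, i)
        couple(j, k)

    if spec.gap_rate > 0:
        gaps = rng.random((n_unique, spec.L)) < spec.gap_rate
        idx[gaps] = GAP_INDEX

    if spec.N > n_unique:
        sources = rng.integers(0, n_unique, size=spec.N - n_unique)
        idx = np.vstack([idx, idx[sources]])

    symbols = np.array(list(AMINO_ACIDS + GAP))
    sequences = ["".join(row) for row in symbols[idx]]
    ids = [f"synth{i + 1:05d}" for i in range(spec.N)]
    msa = MSA(sequences=sequences, ids=ids)
    truth = SyntheticTruth(
        planted_pairs=spec.truth_pairs,
        chained_triples=list(spec.chained_triples),
        spec=spec,
    )
    return msa, truth
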