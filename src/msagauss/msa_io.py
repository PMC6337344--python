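"""Reading, validation and cleanup of multiple sequence alignments.

An alignment is N equal-length sequences over the 20 standard amino acids
plus a gap character.  On input every symbol is uppercased, '.' and '-' both
map to the gap, and ambiguity codes (B, Z, X, J, O, U) map to the gap as
well, so that downstream numeric encodings (gap = zero vector) stay exact.
A2M lowercase (insert-state) columns are uppercased and kept: the model
consumes fixed-width alignments and any column filtering is a preprocessing
concern outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_TO_INDEX, AMBIGUOUS_CODES, AMINO_ACIDS, GAP, GAP_INDEX


class MSAError(ValueError):
    """Invalid alignment input (ragged, empty, or unknown symbols)."""


@dataclass
class MSA:
    """An aligned set of sequences over the canonical 21-symbol alphabet.

    Attributes
    ----------
    sequences : list of str
        Equal-length strings over ``AMINO_ACIDS`` + ``GAP``.
    ids : list of str
        One identifier per sequence.
    """

    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MSAError("alignment contains no sequences")
        if not self.ids:
            self.ids = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise MSAError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise MSAError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.L < 1:
            raise MSAError("alignment length must be at least 1")
        valid = set(AMINO_ACIDS + GAP)
        for rid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - valid
            if bad:
                raise MSAError(f"sequence {rid!r}: invalid symbols {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def to_indices(self) -> np.ndarray:
        """Integer matrix (N, L): amino acids 0..19 in alphabet order, gap 20."""
        lut = np.full(128, -1, dtype=np.int8)
        for aa, i in AA_TO_INDEX.items():
            lut[ord(aa)] = i
        lut[ord(GAP)] = GAP_INDEX
        buf = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return lut[buf].reshape(self.N, self.L).astype(np.int64)

    def gap_fractions(self) -> np.ndarray:
        return (self.to_indices() == GAP_INDEX).mean(axis=1)


def _canonicalize(raw: str, rid: str) -> str:
    out = []
    for ch in raw.upper():
        if ch == "." or ch == "-":
            out.append(GAP)
        elif ch in AMBIGUOUS_CODES:
            out.append(GAP)
        elif ch in AA_TO_INDEX:
            out.append(ch)
        else:
            raise MSAError(f"sequence {rid!r}: unknown symbol {ch!r}")
    return "".join(out)


def read_msa(path: str | Path, format: str = "fasta") -> MSA:
    """Read an alignment from a FASTA or A2M file.

    A2M files are FASTA-formatted; lowercase insert columns are uppercased
    and kept, and '.' becomes the gap.
    """
    if format not in ("fasta", "a2m"):
        raise ValueError(f"unsupported alignment format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MSAError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    sequences = [_canonicalize(str(r.seq), r.id) for r in records]
    return MSA(sequences=sequences, ids=ids)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an alignment as FASTA (canonical symbols only)."""
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(msa.ids, msa.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def clean_msa(msa: MSA, max_gap_fraction: float = 0.9) -> MSA:
    """Drop sequences whose gap fraction strictly exceeds ``max_gap_fraction``.

    The boundary is inclusive on the keep side: a sequence with exactly the
    threshold fraction of gaps is retained.  Order is preserved.
    """
    keep = msa.gap_fractions() <= max_gap_fraction
    if not keep.any():
        raise MSAError(
            "all sequences exceed the gap-fraction threshold "
            f"({max_gap_fraction:g}); nothing left to model"
        )
    return MSA(
        sequences=[s for s, k in zip(msa.sequences, keep) if k],
        ids=[i for i, k in zip(msa.ids, keep) if k],
    )
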