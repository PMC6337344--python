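"""Amino-acid numeric encodings and MSA-to-matrix conversion.

Three encoding families are provided:

* ``binary20_encoding`` — each amino acid is a 20-D indicator vector
  (r_i(k) = delta_ik), the representation used by sparse-inverse and
  Gaussian DCA methods.
* ``property_encoding`` — 1-D encodings from AAindex1 physicochemical
  scales (one real value per amino acid).
* ``blosum_pca_encoding`` — k-D coordinates of each amino acid along the
  top-k principal components of a substitution matrix, treating each row
  of the matrix as a point in 20-D space.

Whatever the encoding, the gap maps to the zero vector, so an aligned
sequence of length L becomes a real vector of length L*s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AA_TO_INDEX, AMINO_ACIDS, GAP_INDEX
from .msa_io import MSA

#: AAindex1 "I" record column order (two lines of ten values each).
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class Encoding:
    """A map from the 20 amino acids to length-s real vectors; gap -> zeros."""

    label: str
    matrix: np.ndarray  # (20, s), rows in AMINO_ACIDS order

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != 20:
            raise ValueError("encoding must define exactly 20 amino-acid vectors")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("encoding vectors must be finite")

    @property
    def s(self) -> int:
        return self.matrix.shape[1]

    def vector(self, symbol: str) -> np.ndarray:
        """Vector for one symbol; the gap returns zeros."""
        if symbol == "-":
            return np.zeros(self.s)
        return self.matrix[AA_TO_INDEX[symbol]].copy()

    def extended_matrix(self) -> np.ndarray:
        """(21, s) lookup table with the gap row (zeros) appended."""
        return np.vstack([self.matrix, np.zeros((1, self.s))])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for aa, row in zip(AMINO_ACIDS, self.matrix):
                fh.write(aa + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class EncodedMSA:
    """Numeric view of an alignment: X has one length-L*s row per sequence."""

    X: np.ndarray
    encoding: Encoding
    msa: MSA

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.msa.L

    @property
    def s(self) -> int:
        return self.encoding.s


def binary20_encoding() -> Encoding:
    """Indicator (one-hot) encoding: amino acid i -> e_i in R^20."""
    return Encoding(label="binary20", matrix=np.eye(20))


@dataclass
class PropertyIndex:
    """One AAindex1 scale: a real value per amino acid plus cluster metadata.

    ``cluster`` is one of A (helix/turn propensity), B (beta propensity),
    C (composition), H (hydrophobicity), P (physicochemical), O (other),
    or None when unknown.
    """

    accession: str
    values: dict[str, float]
    cluster: str | None = None
    description: str = ""
    usable: bool = True

    def value(self, aa: str) -> float:
        return self.values[aa]


def load_aaindex1(path: str | Path) -> list[PropertyIndex]:
    """Parse an AAindex1 flat file (H/D/I record structure).

    The ``I`` record header is followed by two lines of ten values in the
    standard A R N D C Q E G H I / L K M F P S T W Y V column order.
    Entries with any ``NA`` value are returned flagged unusable rather than
    silently imputed.
    """
    entries: list[PropertyIndex] = []
    accession, description, cluster = "", "", None
    tokens: list[str] | None = None

    def flush() -> None:
        nonlocal accession, description, cluster, tokens
        if tokens is None:
            return
        if len(tokens) != 20:
            raise ValueError(
                f"AAindex entry {accession!r}: I record has {len(tokens)} values, expected 20"
            )
        usable = True
        values: dict[str, float] = {}
        for aa, tok in zip(AAINDEX_ORDER, tokens):
            if tok.upper() == "NA":
                usable = False
                values[aa] = float("nan")
            else:
                try:
                    values[aa] = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"AAindex entry {accession!r}: malformed value {tok!r}"
                    ) from exc
        entries.append(
            PropertyIndex(
                accession=accession,
                values=values,
                cluster=cluster,
                description=description,
                usable=usable,
            )
        )
        accession, description, cluster, tokens = "", "", None, None

    with open(path) as fh:
        in_i = False
        for line in fh:
            if line.startswith("//"):
                flush()
                in_i = False
            elif line.startswith("H "):
                accession = line[2:].strip()
                in_i = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_i = False
            elif line.startswith("* cluster:"):
                cluster = line.split(":", 1)[1].strip() or None
                in_i = False
            elif line.startswith("I "):
                tokens = []
                in_i = True
            elif in_i and (line.startswith(" ") or line.startswith("\t")):
                assert tokens is not None
                tokens.extend(line.split())
            else:
                in_i = False
    flush()
    return entries


def property_encoding(index: PropertyIndex) -> Encoding:
    """1-D encoding: amino acid a -> (value(a),); gap -> (0,)."""
    if not index.usable:
        raise ValueError(
            f"AAindex entry {index.accession!r} has missing values and cannot be used"
        )
    col = np.array([[index.value(aa)] for aa in AMINO_ACIDS])
    return Encoding(label=f"aaindex:{index.accession}", matrix=col)


@dataclass
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid substitution matrix (AMINO_ACIDS order)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError(f"substitution matrix {self.name!r} is not symmetric")


def load_blosum(name: str) -> SubstitutionMatrix:
    """Load a named BLOSUM matrix (e.g. ``BLOSUM62``) from Biopython's data."""
    m = substitution_matrices.load(name.upper())
    alpha = str(m.alphabet)
    idx = [alpha.index(aa) for aa in AMINO_ACIDS]
    arr = np.asarray(m)[np.ix_(idx, idx)]
    return SubstitutionMatrix(name=name.upper(), matrix=arr)


def load_substitution_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Read a square matrix in the standard text format.

    The format is one header row of residue letters, then one row per
    residue beginning with its letter; '#' lines are comments.  Columns
    beyond the 20 standard amino acids (B, Z, X, *) are ignored.
    """
    rows: dict[str, dict[str, float]] = {}
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\s+", line)
            if header is None:
                header = parts
                continue
            letter, vals = parts[0], parts[1:]
            if len(vals) != len(header):
                raise ValueError(f"matrix row {letter!r} has {len(vals)} values, expected {len(header)}")
            rows[letter] = {c: float(v) for c, v in zip(header, vals)}
    if header is None:
        raise ValueError(f"no matrix found in {path}")
    missing = [aa for aa in AMINO_ACIDS if aa not in rows or aa not in header]
    if missing:
        raise ValueError(f"matrix is missing residues {missing}")
    arr = np.array([[rows[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS])
    return SubstitutionMatrix(name=name or Path(path).stem.upper(), matrix=arr)


def pca_embed(points: np.ndarray, k: int) -> np.ndarray:
    """Project n points (rows) onto their top-k principal components.

    Points are column-centered; the sample covariance uses the 1/n divisor
    (rankings downstream are invariant to this global scale).  Components
    are ordered by descending eigenvalue and each eigenvector's sign is
    fixed so that its largest-magnitude loading is positive, making the
    embedding deterministic.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= points.shape[1]:
        raise ValueError(f"k={k} out of range 1..{points.shape[1]}")
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / n
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:k]
    components = eigvec[:, order]
    for j in range(components.shape[1]):
        i = np.argmax(np.abs(components[:, j]))
        if components[i, j] < 0:
            components[:, j] = -components[:, j]
    return centered @ components


def blosum_pca_encoding(matrix: SubstitutionMatrix, k: int) -> Encoding:
    """k-D encoding from the principal components of a substitution matrix.

    Each amino acid's matrix row is a point in 20-D space; its encoding is
    the point's coordinates along the top-k principal components of the
    centered point cloud (raw projections, not whitened).
    """
    coords = pca_embed(matrix.matrix, k)
    return Encoding(label=f"{matrix.name.lower()}:pca:{k}", matrix=coords)


def encode_msa(msa: MSA, encoding: Encoding) -> EncodedMSA:
    """Replace every symbol by its encoding vector; rows have length L*s."""
    idx = msa.to_indices()
    table = encoding.extended_matrix()
    X = table[idx].reshape(msa.N, msa.L * encoding.s)
    return EncodedMSA(X=X, encoding=encoding, msa=msa)
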