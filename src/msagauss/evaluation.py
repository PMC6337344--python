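"""Scoring predictions against a reference structure.

A contact is a residue pair whose minimum heavy-atom (non-hydrogen)
distance is strictly below a threshold (8 Angstrom by default).  Ranked
predictions are summarized by the precision curve PPV(k) — the fraction of
the top-k predicted pairs that are true contacts — and by AUC200, the sum
of PPV(k) over k = 1..200 (200 for a perfect prediction).  Two sets of
per-family PPV curves are compared with a two-tailed two-sample t-test at
every k; the curves are declared statistically different only if every
per-k p-value falls below the significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .alphabet import GAP
from .msa_io import MSA
from .scoring import ContactPrediction

DEFAULT_CONTACT_THRESHOLD = 8.0


@dataclass
class ContactMap:
    """Unordered residue pairs in contact, stored with k < l (1-based)."""

    pairs: set[tuple[int, int]]
    n_residues: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        clean = set()
        for k, l in self.pairs:
            if k == l:
                raise ValueError(f"self-pair ({k},{l}) is not a contact")
            clean.add((min(k, l), max(k, l)))
        self.pairs = clean

    def __contains__(self, pair: tuple[int, int]) -> bool:
        k, l = pair
        return (min(k, l), max(k, l)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tl\n")
            for k, l in sorted(self.pairs):
                fh.write(f"{k}\t{l}\n")


def contact_map_from_structure(
    path: str | Path, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> ContactMap:
    """Contact map from PDB ATOM records (first model, first chain).

    Residues are numbered 1..n in order of appearance.  Hydrogens (and
    deuteriums) are excluded; a residue with no heavy atoms is skipped with
    a warning.  The distance criterion is strict: exactly ``threshold`` is
    not a contact.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")
    chains = list(models[0])
    if not chains:
        raise ValueError(f"no chains found in {path}")
    coords: list[np.ndarray] = []
    for residue in chains[0]:
        heavy = [
            atom.coord
            for atom in residue
            if (atom.element or "").upper() not in ("H", "D")
        ]
        if not heavy:
            warnings.warn(f"residue {residue.get_id()} has no heavy atoms; skipped")
            continue
        coords.append(np.asarray(heavy, dtype=float))
    if not coords:
        raise ValueError(f"no residues with heavy atoms in {path}")
    n = len(coords)
    pairs = set()
    for k in range(n):
        for l in range(k + 1, n):
            d = np.linalg.norm(coords[k][:, None, :] - coords[l][None, :, :], axis=2)
            if d.min() < threshold:
                pairs.add((k + 1, l + 1))
    return ContactMap(pairs=pairs, n_residues=n, threshold=threshold)


def contact_map_from_tsv(path: str | Path) -> ContactMap:
    """Contact list from a TSV with columns k, l (header optional)."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                k, l = int(fields[0]), int(fields[1])
            except ValueError:
                continue  # header line
            pairs.add((min(k, l), max(k, l)))
    if not pairs:
        raise ValueError(f"no contact pairs found in {path}")
    return ContactMap(pairs=pairs)


def reference_column_mapping(msa: MSA) -> dict[int, int]:
    """Map alignment columns to residue indices of the reference sequence.

    The reference is the first sequence of the alignment; columns where it
    carries a gap have no structural counterpart and are excluded.  Both
    sides are 1-based.
    """
    ref = msa.sequences[0]
    mapping: dict[int, int] = {}
    res = 0
    for col, sym in enumerate(ref, start=1):
        if sym != GAP:
            res += 1
            mapping[col] = res
    return mapping


@dataclass
class PPVResult:
    """Precision curve PPV(k) and its partial sum AUC200."""

    ppv: np.ndarray
    auc200: float
    n_predictions: int
    truncated: bool = False  # fewer than 200 predictions were available

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tppv\n")
            for k, v in enumerate(self.ppv, start=1):
                fh.write(f"{k}\t{v:.10g}\n")


def ppv_curve(
    prediction: ContactPrediction, truth: ContactMap, k_max: int = 200
) -> PPVResult:
    """PPV(k) = true positives among the top k, for k = 1..len(prediction).

    AUC200 sums PPV(k) over k = 1..min(k_max, available predictions); when
    fewer than k_max predictions exist no extrapolation is applied and the
    result is flagged truncated.
    """
    if len(prediction) == 0:
        raise ValueError("cannot evaluate an empty prediction")
    if truth.n_residues is not None:
        bad = [p for p in prediction.pairs if p[1] > truth.n_residues]
        if bad:
            raise ValueError(
                f"prediction indices {bad[:3]} exceed the {truth.n_residues} "
                "residues of the reference structure (index-space mismatch)"
            )
    hits = np.array([1.0 if p in truth else 0.0 for p in prediction.pairs])
    ppv = np.cumsum(hits) / np.arange(1, len(hits) + 1)
    auc = float(ppv[:k_max].sum())
    return PPVResult(
        ppv=ppv,
        auc200=auc,
        n_predictions=len(prediction),
        truncated=len(prediction) < k_max,
    )


def compare_ppv_sets(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
):
    """Per-k two-tailed two-sample t-test between two sets of PPV curves.

    Inputs are (n_families, K) arrays with matching shapes.  The pooled
    (equal-variance) test is the default; ``welch=True`` drops the equal
    variance assumption.  Returns (t, p, verdict) where the verdict is
    ``"different"`` only if every per-k p-value is below ``alpha``, and
    ``"indistinguishable"`` otherwise.  Degenerate columns (zero variance
    in both groups) yield t=0, p=1 when the means agree.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"family counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"k ranges differ: {a.shape[1]} vs {b.shape[1]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t[degenerate & same_mean] = 0.0
    p[degenerate & same_mean] = 1.0
    t[degenerate & ~same_mean] = np.inf
    p[degenerate & ~same_mean] = 0.0
    verdict = "different" if bool(np.all(p < alpha)) else "indistinguishable"
    return t, p, verdict
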