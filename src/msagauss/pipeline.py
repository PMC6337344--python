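"""End-to-end contact prediction pipeline and parameter sweeps.

One call runs the whole chain: clean the alignment, reweight sequences,
encode, fit the Gaussian model, extract and gauge-correct coupling
scores, APC-correct, and rank.  The cli module is a thin shell over these
functions.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encodings import (
    Encoding,
    binary20_encoding,
    blosum_pca_encoding,
    encode_msa,
    load_aaindex1,
    load_blosum,
    load_substitution_matrix,
    property_encoding,
)
from .evaluation import ContactMap, PPVResult, ppv_curve
from .gaussian_model import GaussianModel, fit_gaussian_model
from .msa_io import MSA, clean_msa
from .scoring import ContactPrediction, apc_correct, rank_contacts, score_matrix
from .weighting import DEFAULT_FIXED_R, WeightingResult, sequence_weights, similarity_cutoff

#: Meff bin edges for small / medium / large families
MEFF_BINS = (500.0, 1000.0)


def default_lambda(s: int) -> float:
    """Per-encoding default prior weight.

    0.8 for the 20-D binary encoding (the empirical optimum for that
    representation); smaller for lower-dimensional encodings, growing with
    the dimension since larger covariance matrices are more under-sampled
    (0.5 around k=3, 0.7 around k=11).
    """
    if s >= 20:
        return 0.8
    if s == 1:
        return 0.2
    return float(np.clip(round(0.4 + 0.03 * s, 2), 0.3, 0.8))


def parse_encoding_spec(spec: str, aaindex_path: str | None = None) -> Encoding:
    """Build an encoding from a CLI-style spec string.

    Accepted forms: ``binary20``; ``aaindex:<ACCESSION>`` (requires
    ``aaindex_path``); ``blosum62:pca:11`` (any Biopython-shipped BLOSUM);
    ``matrixfile:<path>:pca:<k>`` for a user-supplied square matrix file.
    """
    parts = spec.split(":")
    if spec == "binary20":
        return binary20_encoding()
    if parts[0] == "aaindex":
        if len(parts) != 2:
            raise ValueError(f"bad aaindex spec {spec!r}; expected aaindex:<ACCESSION>")
        if aaindex_path is None:
            raise ValueError("aaindex encodings need an AAindex1 flat file (aaindex_path)")
        accession = parts[1]
        for entry in load_aaindex1(aaindex_path):
            if entry.accession.split()[0] == accession:
                return property_encoding(entry)
        raise ValueError(f"accession {accession!r} not found in {aaindex_path}")
    if parts[0].startswith("blosum") and len(parts) == 3 and parts[1] == "pca":
        return blosum_pca_encoding(load_blosum(parts[0]), int(parts[2]))
    if parts[0] == "matrixfile" and len(parts) == 4 and parts[2] == "pca":
        return blosum_pca_encoding(load_substitution_matrix(parts[1]), int(parts[3]))
    raise ValueError(f"unrecognized encoding spec {spec!r}")


@dataclass
class RunConfig:
    """Validated parameters of one prediction run."""

    encoding: str = "binary20"
    aaindex_path: str | None = None
    lam: float | None = None  # None -> per-encoding default
    reweight: str = "auto"  # auto | fixed | none
    fixed_r: float = DEFAULT_FIXED_R
    max_gap_fraction: float = 0.9
    min_separation: int = 4
    top_k: int = 200
    ridge: str | float | None = "auto"

    def __post_init__(self) -> None:
        if self.lam is not None and not 0 <= self.lam <= 1:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.reweight not in ("auto", "fixed", "none"):
            raise ValueError(f"reweight must be auto|fixed|none, got {self.reweight!r}")
        if self.min_separation < 0 or self.top_k < 1:
            raise ValueError("min_separation must be >= 0 and top_k >= 1")

    def to_dict(self) -> dict:
        return {
            "encoding": self.encoding,
            "aaindex_path": self.aaindex_path,
            "lambda": self.lam,
            "reweight": self.reweight,
            "fixed_r": self.fixed_r,
            "max_gap_fraction": self.max_gap_fraction,
            "min_separation": self.min_separation,
            "top_k": self.top_k,
            "ridge": self.ridge,
        }


@dataclass
class PredictionRun:
    """Everything produced by one pass of the pipeline."""

    contacts: ContactPrediction
    raw_scores: np.ndarray
    apc_scores: np.ndarray
    model: GaussianModel
    weighting: WeightingResult
    config: RunConfig
    n_sequences_kept: int
    elapsed_seconds: float = 0.0

    @property
    def meff(self) -> float:
        return self.weighting.meff

    def metadata(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "encoding_label": self.model.encoding_label,
            "lambda": self.model.lam,
            "ridge_epsilon": self.model.epsilon,
            "similarity_cutoff": self.weighting.r,
            "meff": self.meff,
            "n_sequences_kept": self.n_sequences_kept,
            "L": self.model.L,
            "s": self.model.s,
            "elapsed_seconds": self.elapsed_seconds,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.contacts.to_tsv(outdir / "contacts.tsv")
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def predict_contacts(
    msa: MSA, config: RunConfig | None = None, encoding: Encoding | None = None
) -> PredictionRun:
    """Run the full pipeline on one alignment.

    ``encoding`` overrides the config's encoding spec when given (useful
    when the encoding object was built programmatically).
    """
    t0 = time.perf_counter()
    config = config or RunConfig()
    if encoding is None:
        encoding = parse_encoding_spec(config.encoding, config.aaindex_path)
    msa = clean_msa(msa, config.max_gap_fraction)
    if config.reweight == "none":
        weighting = WeightingResult(
            weights=np.ones(msa.N),
            neighbor_counts=np.ones(msa.N, dtype=np.int64),
            r=1.0,
        )
    else:
        r = similarity_cutoff(msa, mode=config.reweight, fixed_r=config.fixed_r)
        weighting = sequence_weights(msa, r)
    encoded = encode_msa(msa, encoding)
    lam = config.lam if config.lam is not None else default_lambda(encoding.s)
    model = fit_gaussian_model(encoded, weighting, lam=lam, ridge=config.ridge)
    raw = score_matrix(model.J, msa.L, encoding.s)
    apc = apc_correct(raw)
    contacts = rank_contacts(
        apc, raw, min_separation=config.min_separation, top_k=config.top_k
    )
    return PredictionRun(
        contacts=contacts,
        raw_scores=raw,
        apc_scores=apc,
        model=model,
        weighting=weighting,
        config=config,
        n_sequences_kept=msa.N,
        elapsed_seconds=time.perf_counter() - t0,
    )


def evaluate_prediction(
    contacts: ContactPrediction, truth: ContactMap, k_max: int = 200
) -> PPVResult:
    """PPV curve and AUC200 of a ranked prediction against a contact map."""
    return ppv_curve(contacts, truth, k_max=k_max)


def meff_bin(meff: float) -> str:
    """Small / medium / large family label from Meff."""
    if meff < MEFF_BINS[0]:
        return "small"
    if meff < MEFF_BINS[1]:
        return "medium"
    return "large"


def sweep(
    families: list[tuple[MSA, ContactMap]],
    encodings: list[Encoding] | None = None,
    lambdas: list[float] | None = None,
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Grid evaluation: mean AUC200 per (encoding, lambda) cell.

    Returns a tidy DataFrame with one row per family and cell, carrying the
    AUC200, Meff, Meff bin and alignment length, plus per-cell means under
    ``groupby``-friendly columns.
    """
    if not families:
        raise ValueError("sweep needs at least one (MSA, truth) family")
    base = base_config or RunConfig()
    encodings = encodings or [parse_encoding_spec(base.encoding, base.aaindex_path)]
    lambdas = lambdas if lambdas is not None else [base.lam]
    if not lambdas or not encodings:
        raise ValueError("empty sweep grid")
    rows = []
    for enc in encodings:
        for lam in lambdas:
            cfg = RunConfig(
                encoding=enc.label,
                aaindex_path=base.aaindex_path,
                lam=lam,
                reweight=base.reweight,
                fixed_r=base.fixed_r,
                max_gap_fraction=base.max_gap_fraction,
                min_separation=base.min_separation,
                top_k=base.top_k,
                ridge=base.ridge,
            )
            for fam_id, (msa, truth) in enumerate(families):
                run = predict_contacts(msa, cfg, encoding=enc)
                result = evaluate_prediction(run.contacts, truth, k_max=base.top_k)
                rows.append(
                    {
                        "family": fam_id,
                        "encoding": enc.label,
                        "lambda": lam,
                        "auc200": result.auc200,
                        "meff": run.meff,
                        "meff_bin": meff_bin(run.meff),
                        "L": msa.L,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean AUC200, overall and broken down by Meff bin."""
    overall = (
        table.groupby(["encoding", "lambda"], as_index=False)["auc200"]
        .mean()
        .assign(meff_bin="all")
    )
    by_bin = table.groupby(["encoding", "lambda", "meff_bin"], as_index=False)[
        "auc200"
    ].mean()
    return pd.concat([overall, by_bin], ignore_index=True)[
        ["encoding", "lambda", "meff_bin", "auc200"]
    ]
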