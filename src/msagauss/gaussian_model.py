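"""The multivariate Gaussian model of an encoded alignment.

Each encoded sequence X_n (length L*s) is modeled as a draw from a
multivariate Gaussian N(mu, Sigma).  The maximum-likelihood estimates are
the (weighted) empirical mean and covariance of the alignment; because the
empirical covariance is typically rank-deficient, it is blended with a
block-diagonal prior derived from a uniform distribution over the 20 amino
acids:

    CM = lambda*CP + (1-lambda)*Cbar + lambda*(1-lambda) * outer(Xbar - muP)

The coupling matrix J = CM^-1 (the precision matrix) captures conditional
dependencies between positions; its off-diagonal s x s blocks are the
direct couplings from which contacts are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .encodings import EncodedMSA, Encoding
from .weighting import WeightingResult

#: ridge ladder: epsilon = RIDGE_BASE * mean(diag) * 10^t, t = 0..RIDGE_STEPS-1
RIDGE_BASE = 1e-8
RIDGE_STEPS = 7


class SingularModelError(LinAlgError):
    """Corrected covariance could not be factorized even with the ridge ladder."""


@dataclass
class PriorSpec:
    """Uniform-amino-acid prior: mean r_bar and covariance Cr per position.

    The full-alignment prior has mean muP (L copies of r_bar) and a
    block-diagonal covariance CP with Cr on every position block — the
    prior carries no inter-position information by construction.
    """

    r_bar: np.ndarray  # (s,)
    c_r: np.ndarray  # (s, s)
    L: int

    @property
    def s(self) -> int:
        return self.r_bar.shape[0]

    @property
    def mu(self) -> np.ndarray:
        return np.tile(self.r_bar, self.L)

    @property
    def cp(self) -> np.ndarray:
        return np.kron(np.eye(self.L), self.c_r)


def build_prior(encoding: Encoding, L: int) -> PriorSpec:
    """Mean and covariance of an amino acid drawn uniformly over the 20 types."""
    vecs = encoding.matrix
    r_bar = vecs.mean(axis=0)
    diffs = vecs - r_bar
    c_r = diffs.T @ diffs / 20.0
    return PriorSpec(r_bar=r_bar, c_r=c_r, L=int(L))


def _as_weight_array(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    if isinstance(weights, WeightingResult):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return w


def weighted_mean_cov(encoded: EncodedMSA, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted empirical mean and covariance of the encoded alignment.

    With ``weights=None`` (uniform) this reduces exactly to the unweighted
    empirical mean and covariance; the unweighted case is not a separate
    code path.
    """
    X = encoded.X
    w = _as_weight_array(weights, X.shape[0])
    wsum = w.sum()
    xbar = w @ X / wsum
    xc = X - xbar
    cbar = (xc * w[:, None]).T @ xc / wsum
    cbar = 0.5 * (cbar + cbar.T)
    return xbar, cbar


def corrected_covariance(
    xbar: np.ndarray, cbar: np.ndarray, prior: PriorSpec, lam: float
) -> np.ndarray:
    """Blend the empirical covariance with the uniform prior (weight lambda).

    At the endpoints the result is exactly Cbar (lambda=0) or CP (lambda=1);
    in between a rank-one term accounts for the difference of the means.
    """
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if lam == 0:
        return cbar.copy()
    if lam == 1:
        return prior.cp
    d = xbar - prior.mu
    return lam * prior.cp + (1 - lam) * cbar + lam * (1 - lam) * np.outer(d, d)


def coupling_matrix(cm: np.ndarray, ridge="auto") -> tuple[np.ndarray, float]:
    """Invert the corrected covariance: J = (CM + eps*I)^-1.

    ``ridge`` policy:

    * ``"auto"`` — try eps = 0 first, then climb a geometric ladder
      starting at 1e-8 times the mean diagonal until the Cholesky
      factorization succeeds.
    * ``"none"`` / ``None`` — exact inversion only; singular input raises.
    * a float — use exactly that epsilon.

    Returns (J, eps_used); the epsilon actually applied is part of the
    model record so results stay auditable.
    """
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    base = float(np.abs(np.diag(cm)).mean())
    if base == 0:
        base = 1.0
    if ridge == "auto":
        ladder = [0.0] + [RIDGE_BASE * base * 10**t for t in range(RIDGE_STEPS)]
    elif ridge in (None, "none"):
        ladder = [0.0]
    else:
        ladder = [float(ridge)]
    eye = np.eye(n)
    for eps in ladder:
        try:
            factor = cho_factor(cm + eps * eye, lower=True, check_finite=False)
        except LinAlgError:
            continue
        J = cho_solve(factor, eye, check_finite=False)
        return 0.5 * (J + J.T), eps
    raise SingularModelError(
        "corrected covariance is singular; increase lambda or allow a ridge "
        "(ridge='auto')"
    )


def gaussian_log_likelihood(encoded, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log-likelihood of the encoded sequences under N(mu, Sigma).

    Sequences are treated as independent draws, so the value is the sum of
    the per-sequence Gaussian log-densities.  Sigma must be positive
    definite.
    """
    X = encoded.X if isinstance(encoded, EncodedMSA) else np.asarray(encoded, dtype=float)
    X = np.atleast_2d(X)
    n, d = X.shape
    try:
        factor = cho_factor(sigma, lower=True)
    except LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    diff = X - mu
    solved = cho_solve(factor, diff.T)
    quad = float(np.sum(diff.T * solved))
    return -0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad)


@dataclass
class GaussianModel:
    """Fitted model: empirical moments, corrected covariance and couplings."""

    xbar: np.ndarray
    cbar: np.ndarray
    lam: float
    cm: np.ndarray
    J: np.ndarray
    epsilon: float
    prior: PriorSpec
    encoding_label: str

    @property
    def L(self) -> int:
        return self.prior.L

    @property
    def s(self) -> int:
        return self.prior.s


def fit_gaussian_model(
    encoded: EncodedMSA, weights=None, lam: float = 0.8, ridge="auto"
) -> GaussianModel:
    """Full model fit: moments, prior blend, and precision matrix."""
    prior = build_prior(encoded.encoding, encoded.L)
    xbar, cbar = weighted_mean_cov(encoded, weights)
    cm = corrected_covariance(xbar, cbar, prior, lam)
    J, eps = coupling_matrix(cm, ridge=ridge)
    return GaussianModel(
        xbar=xbar,
        cbar=cbar,
        lam=float(lam),
        cm=cm,
        J=J,
        epsilon=eps,
        prior=prior,
        encoding_label=encoded.encoding.label,
    )
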