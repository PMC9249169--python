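"""Data model and log-density primitives of the hierarchical latent-correlation model.

For every genomic feature ``j`` the model ties the two observed molecular
layers together through a per-cell bivariate Gaussian latent state::

    X_i = (X_i1, X_i2) ~ N(mu, Sigma),   Sigma = [[s1^2, rho*s1*s2],
                                                  [rho*s1*s2, s2^2]]

The first coordinate feeds a zero-inflated Poisson (ZIP) count likelihood
with exponential link and known cell scaling factors; the second feeds a
binomial likelihood whose success probability is the probit transform of the
latent state.  Everything here is pure computation; sampling lives in
:mod:`latentcorr.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import betaln, gammaln, log_ndtr, logsumexp

__all__ = [
    "FeatureData",
    "FeatureParams",
    "Hyperparams",
    "zip_log_pmf",
    "binom_probit_log_pmf",
    "latent_log_density",
    "log_prior",
    "joint_log_posterior",
]

_LOG_FLOOR = -35.0  # probabilities are clamped at exp(-35) before taking logs


@dataclass
class FeatureData:
    """Paired observations for one feature across ``I`` cells.

    Attributes
    ----------
    feature_id : str
        Identifier of the feature (e.g. a gene / promoter pair).
    y1 : ndarray of int
        Raw expression read counts per cell.
    y2 : ndarray of int
        Methylated-CpG (or open-peak) counts per cell.
    n : ndarray of int
        Per-cell coverage: total CpG reads (or total peaks). ``n[i] == 0``
        marks missing epigenome information for that cell.
    s : ndarray of float
        Known positive cell scaling factors (expression offsets).
    """

    feature_id: str
    y1: np.ndarray
    y2: np.ndarray
    n: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.s = np.asarray(self.s, dtype=np.float64)
        lengths = {arr.shape for arr in (self.y1, self.y2, self.n, self.s)}
        if len(lengths) != 1 or self.y1.ndim != 1:
            raise ValueError("y1, y2, n, s must be 1-d arrays of equal length")
        if self.n_cells < 2:
            raise ValueError("need at least two cells per feature")
        if np.any(self.y1 < 0):
            raise ValueError("expression counts must be non-negative")
        if np.any(self.y2 < 0) or np.any(self.y2 > self.n):
            raise ValueError("need 0 <= y2 <= n for every cell")
        if np.any(~np.isfinite(self.s)) or np.any(self.s <= 0):
            raise ValueError("scaling factors must be positive and finite")

    @property
    def n_cells(self) -> int:
        return self.y1.shape[0]

    def permuted(self, order: np.ndarray) -> "FeatureData":
        """Return a copy with all per-cell arrays reindexed by ``order``."""
        return FeatureData(
            feature_id=self.feature_id,
            y1=self.y1[order],
            y2=self.y2[order],
            n=self.n[order],
            s=self.s[order],
        )


@dataclass
class FeatureParams:
    """Per-feature parameter vector, optionally with the latent matrix."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float
    pi: float
    X: np.ndarray | None = None  # I x 2 latent states
    dropout: np.ndarray | None = None  # simulation truth: structural-zero flags

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("latent standard deviations must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("latent correlation must lie in (-1, 1)")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("zero-inflation probability must lie in [0, 1]")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=np.float64)
            if self.X.ndim != 2 or self.X.shape[1] != 2:
                raise ValueError("latent matrix X must have shape (I, 2)")

    @property
    def cov(self) -> np.ndarray:
        off = self.rho * self.sigma1 * self.sigma2
        return np.array(
            [[self.sigma1**2, off], [off, self.sigma2**2]], dtype=np.float64
        )


def _default_m() -> np.ndarray:
    return np.array([4.0, 0.0])


def _default_H() -> np.ndarray:
    return np.eye(2)


@dataclass
class Hyperparams:
    """Prior hyper-parameters shared across features.

    Defaults: Beta(2, 8) on the zero-inflation probability, N((4, 0), I) on
    the latent means, inverse-Gamma(2.5, 4.5) on each latent standard
    deviation, and a Beta(15, 15) rescaled to [-1, 1] on the correlation.
    """

    a: float = 2.0
    b: float = 8.0
    m: np.ndarray = field(default_factory=_default_m)
    H: np.ndarray = field(default_factory=_default_H)
    c1: float = 2.5
    c2: float = 4.5
    d1: float = 15.0
    d2: float = 15.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64)
        self.H = np.asarray(self.H, dtype=np.float64)
        if min(self.a, self.b, self.c1, self.c2, self.d1, self.d2) <= 0:
            raise ValueError("all scalar hyper-parameters must be positive")
        if self.m.shape != (2,) or self.H.shape != (2, 2):
            raise ValueError("m must have shape (2,) and H shape (2, 2)")
        if not np.allclose(self.H, self.H.T):
            raise ValueError("H must be symmetric")
        if np.any(np.linalg.eigvalsh(self.H) <= 0):
            raise ValueError("H must be positive definite")

    def rho_prior_mean(self) -> float:
        """Closed-form mean of the rescaled Beta prior on rho: 2*E[B] - 1."""
        return 2.0 * self.d1 / (self.d1 + self.d2) - 1.0


def zip_log_pmf(y, x, s, pi):
    """Log pmf of the zero-inflated Poisson with rate ``s * exp(x)``.

    ``P(y) = pi * 1{y=0} + (1 - pi) * Poisson(y; s * exp(x))``.  Vectorized
    over all arguments; the ``y = 0`` branch is evaluated by log-sum-exp.
    """
    y = np.asarray(y)
    x = np.asarray(x, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(s <= 0):
        raise ValueError("scaling factors must be positive")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("zero-inflation probability must lie in [0, 1]")

    log_rate = np.log(s) + x
    rate = np.exp(log_rate)
    log_pois = y * log_rate - rate - gammaln(y + 1.0)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(pi, np.exp(_LOG_FLOOR)))
        log1m_pi = np.log1p(-np.minimum(pi, 1.0 - np.exp(_LOG_FLOOR)))
    # y = 0: log(pi + (1-pi) exp(-rate)) via logsumexp of the two branches
    zero_branch = logsumexp(
        np.stack(np.broadcast_arrays(log_pi, log1m_pi - rate), axis=0), axis=0
    )
    out = np.where(y == 0, zero_branch, log1m_pi + log_pois)
    # structural-zero certainty: pi == 1 puts all mass at y == 0
    out = np.where((y == 0) & (pi >= 1.0), 0.0, out)
    out = np.where((y > 0) & (pi >= 1.0), -np.inf, out)
    return out if out.ndim else float(out)


def binom_probit_log_pmf(y, x, n):
    """Log pmf of Binomial(n, Phi(x)) at ``y``; ``n = 0`` is vacuous (0).

    Uses the log normal-CDF so that tails with ``|x| > 8`` stay finite.
    """
    y = np.asarray(y)
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    log_p = log_ndtr(x)
    log_q = log_ndtr(-x)
    log_coef = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    out = log_coef + y * log_p + (n - y) * log_q
    out = np.where(n == 0, 0.0, out)
    return out if out.ndim else float(out)


def latent_log_density(x_pair, params: FeatureParams):
    """Bivariate Gaussian log density of one latent pair under ``params``."""
    x = np.asarray(x_pair, dtype=np.float64)
    mean = np.array([params.mu1, params.mu2])
    return float(
        stats.multivariate_normal.logpdf(x, mean=mean, cov=params.cov)
    )


def scaled_beta_log_pdf(rho, d1: float, d2: float):
    """Log density of a Beta(d1, d2) variable rescaled from [0, 1] to [-1, 1]."""
    rho = np.asarray(rho, dtype=np.float64)
    u = (rho + 1.0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            (d1 - 1.0) * np.log(u)
            + (d2 - 1.0) * np.log1p(-u)
            - betaln(d1, d2)
            - np.log(2.0)
        )
    out = np.where((rho <= -1.0) | (rho >= 1.0), -np.inf, out)
    return out if out.ndim else float(out)


def log_prior(params: FeatureParams, hyper: Hyperparams) -> float:
    """Sum of log prior densities; ``-inf`` outside the support."""
    if not (-1.0 < params.rho < 1.0):
        return -np.inf
    if params.sigma1 <= 0 or params.sigma2 <= 0:
        return -np.inf
    if not 0.0 <= params.pi <= 1.0:
        return -np.inf
    lp = float(stats.beta.logpdf(params.pi, hyper.a, hyper.b))
    mu = np.array([params.mu1, params.mu2])
    lp += float(stats.multivariate_normal.logpdf(mu, mean=hyper.m, cov=hyper.H))
    lp += float(stats.invgamma.logpdf(params.sigma1, hyper.c1, scale=hyper.c2))
    lp += float(stats.invgamma.logpdf(params.sigma2, hyper.c1, scale=hyper.c2))
    lp += float(scaled_beta_log_pdf(params.rho, hyper.d1, hyper.d2))
    return lp


def joint_log_posterior(
    data: FeatureData, params: FeatureParams, hyper: Hyperparams
) -> float:
    """Unnormalized log posterior of one feature, latent states included.

    Sums, over cells, the ZIP expression term at ``X[i, 0]``, the
    binomial-probit term at ``X[i, 1]`` and the latent bivariate-Gaussian
    term, then adds the log prior.
    """
    if params.X is None:
        raise ValueError("params.X is required for the joint posterior")
    if params.X.shape[0] != data.n_cells:
        raise ValueError("latent matrix X and data disagree on cell count")
    ll = float(np.sum(zip_log_pmf(data.y1, params.X[:, 0], data.s, params.pi)))
    ll += float(np.sum(binom_probit_log_pmf(data.y2, params.X[:, 1], data.n)))
    mean = np.array([params.mu1, params.mu2])
    ll += float(
        np.sum(
            stats.multivariate_normal.logpdf(params.X, mean=mean, cov=params.cov)
        )
    )
    return ll + log_prior(params, hyper)
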