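"""Per-feature MCMC inference and convergence diagnostics.

Each feature is fitted independently (the model factorizes across features),
which makes parallel execution embarrassingly simple and lets every feature
own a deterministic seed stream derived from ``(seed, feature_index)``.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit, ndtri

from . import model as _model
from ._kernels import logp_and_grad, pack_hyper
from .model import FeatureData, FeatureParams, Hyperparams
from .nuts import nuts_sample

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "fit_feature",
    "fit_all",
    "gelman_rubin",
    "summarize_posteriors",
]

PARAM_NAMES = ("mu1", "mu2", "sigma1", "sigma2", "rho", "pi")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_samples`` is the total iteration count; the first ``n_burnin``
    iterations are used for adaptation and discarded.
    """

    n_samples: int = 5000
    n_burnin: int = 3000
    target_accept: float = 0.65
    n_chains: int = 4
    seed: int = 0
    max_tree_depth: int = 10
    zero_inflated: bool = True
    keep_latent: bool = False

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be positive")
        if self.n_burnin >= self.n_samples:
            raise ValueError("n_burnin must be smaller than n_samples")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorSamples:
    """Post-burn-in draws for one feature, organised as (chain, draw)."""

    feature_id: str
    draws: dict[str, np.ndarray]  # parameter name -> (n_chains, n_kept)
    rhat: dict[str, float]
    accept_rate: float
    n_divergent: int
    zero_inflated: bool = True
    latent: np.ndarray | None = None  # (n_chains, n_kept, I, 2) when retained
    error: str | None = None

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat draw vector."""
        return self.draws[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.draws[name]))

    def max_rhat(self) -> float:
        return max(self.rhat.values())


def gelman_rubin(draws_by_chain: np.ndarray, split: bool = True) -> float:
    """Potential scale reduction factor R-hat.

    ``draws_by_chain`` has shape (n_chains, n_draws).  With ``split=True``
    every chain is halved first (the split-chain variant), which also flags
    within-chain drift.
    """
    draws = np.asarray(draws_by_chain, dtype=np.float64)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    if split:
        half = draws.shape[1] // 2
        if half < 2:
            raise ValueError("chains too short to split; pass split=False")
        draws = np.vstack([draws[:, :half], draws[:, half : 2 * half]])
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0.0 and b <= 0.0:
        raise ValueError("degenerate chains: zero total variance")
    if w <= 0.0:
        return np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _initial_point(
    data: FeatureData, zero_inflated: bool, rng: np.random.Generator
) -> np.ndarray:
    """Moment-matched start with a small chain-specific jitter.

    Latent states are seeded from per-cell transforms of the observations
    (log counts; probit of observed methylation rates) so the chain starts
    near the typical set rather than at a likelihood cliff.
    """
    I = data.n_cells
    off = 6 if zero_inflated else 5
    dim = off + 2 * I
    q = np.zeros(dim)

    x1 = np.log((data.y1 + 0.5) / data.s)
    mu1 = float(np.mean(x1))
    sigma1 = max(float(np.std(x1)), 0.3)
    rates = (data.y2 + 0.5) / np.maximum(data.n, 1) / (1.0 + 0.5 / np.maximum(data.n, 1))
    x2 = np.where(
        data.n > 0, ndtri(np.clip(rates, 1e-4, 1 - 1e-4)), 0.0
    )
    covered = data.n > 0
    mu2 = float(np.mean(x2[covered])) if covered.any() else 0.0
    sigma2 = max(float(np.std(x2[covered])) if covered.any() else 1.0, 0.3)
    x2 = np.where(covered, x2, mu2)

    q[0] = mu1
    q[1] = mu2
    q[2] = math.log(sigma1)
    q[3] = math.log(sigma2)
    q[4] = 0.0  # atanh rho
    if zero_inflated:
        zero_frac = float(np.mean(data.y1 == 0))
        q[5] = float(logit(np.clip(0.5 * zero_frac, 0.01, 0.9)))
    q[off : off + I] = x1
    q[off + I : off + 2 * I] = x2
    q += 0.05 * rng.standard_normal(dim)
    return q


def _initial_inv_mass(data: FeatureData, zero_inflated: bool) -> np.ndarray:
    """Per-coordinate posterior-variance guesses (inverse mass matrix).

    Latent coordinates use the observation Fisher information: ~``y + c``
    for the Poisson-log layer, ``0.6 n + c`` for the binomial-probit layer;
    global parameters use crude ``1/I`` scalings.  Only order of magnitude
    matters — the burn-in window refines these estimates.
    """
    I = data.n_cells
    off = 6 if zero_inflated else 5
    minv = np.empty(off + 2 * I)
    minv[0] = max(9.0 / I, 1e-3)  # mu1 (sigma1^2 / I at the prior scale)
    minv[1] = max(4.0 / I, 1e-3)
    minv[2] = 1.0 / (2.0 * I)
    minv[3] = 1.0 / (2.0 * I)
    minv[4] = 2.0 / I
    if zero_inflated:
        minv[5] = 0.25
    minv[off : off + I] = 1.0 / (data.y1 + 0.5 + 1.0 / 9.0)
    minv[off + I : off + 2 * I] = 1.0 / (0.6 * data.n + 0.25)
    return minv


def _diagnose_start(
    data: FeatureData, q: np.ndarray, hyper: Hyperparams, zero_inflated: bool
) -> str:
    """Name the log-posterior term that is non-finite at ``q``."""
    I = data.n_cells
    off = 6 if zero_inflated else 5
    sig1, sig2 = math.exp(q[2]), math.exp(q[3])
    rho = math.tanh(q[4])
    pi = 1.0 / (1.0 + math.exp(-q[5])) if zero_inflated else 0.0
    x1 = q[off : off + I]
    x2 = q[off + I : off + 2 * I]
    terms = {
        "zip expression likelihood": np.sum(
            _model.zip_log_pmf(data.y1, x1, data.s, pi)
        ),
        "binomial-probit likelihood": np.sum(
            _model.binom_probit_log_pmf(data.y2, x2, data.n)
        ),
        "prior": _model.log_prior(
            FeatureParams(q[0], q[1], sig1, sig2, rho, pi), hyper
        ),
    }
    bad = [name for name, value in terms.items() if not np.isfinite(value)]
    return ", ".join(bad) if bad else "unknown term"


def fit_feature(
    data: FeatureData,
    hyper: Hyperparams | None = None,
    config: McmcConfig | None = None,
    seed: int | Sequence[int] | None = None,
) -> PosteriorSamples:
    """Sample the per-feature posterior with NUTS.

    Runs ``config.n_chains`` chains with chain-specific seed streams; step
    size is adapted toward ``config.target_accept`` during burn-in.  The
    same data, config and seed always reproduce the draws exactly.
    """
    hyper = hyper or Hyperparams()
    config = config or McmcConfig()
    if seed is None:
        entropy: tuple[int, ...] = (config.seed,)
    elif isinstance(seed, (tuple, list)):
        entropy = tuple(int(v) for v in seed)
    else:
        entropy = (int(seed),)
    hp = pack_hyper(hyper)
    zi = config.zero_inflated
    y1 = np.ascontiguousarray(data.y1, dtype=np.int64)
    y2 = np.ascontiguousarray(data.y2, dtype=np.int64)
    n = np.ascontiguousarray(data.n, dtype=np.int64)
    s = np.ascontiguousarray(data.s, dtype=np.float64)

    def logp_grad(q: np.ndarray):
        return logp_and_grad(q, y1, y2, n, s, hp, zi)

    I = data.n_cells
    off = 6 if zi else 5
    n_kept = config.n_samples - config.n_burnin
    chain_draws = np.empty((config.n_chains, n_kept, off))
    latent = (
        np.empty((config.n_chains, n_kept, I, 2)) if config.keep_latent else None
    )
    accept_rates = []
    n_divergent = 0

    for chain in range(config.n_chains):
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence(entropy + (chain,)))
        )
        q0 = _initial_point(data, zi, rng)
        logp0, _ = logp_grad(q0)
        if not np.isfinite(logp0):
            bad = _diagnose_start(data, q0, hyper, zi)
            raise ValueError(
                f"non-finite log posterior at initialization of feature "
                f"{data.feature_id!r}: {bad}"
            )
        qs, stats = nuts_sample(
            logp_grad,
            q0,
            config.n_samples,
            config.n_burnin,
            rng,
            target_accept=config.target_accept,
            max_depth=config.max_tree_depth,
            minv0=_initial_inv_mass(data, zi),
        )
        chain_draws[chain] = qs[:, :off]
        if latent is not None:
            latent[chain, :, :, 0] = qs[:, off : off + I]
            latent[chain, :, :, 1] = qs[:, off + I : off + 2 * I]
        accept_rates.append(stats.accept_rate)
        n_divergent += stats.n_divergent

    draws = {
        "mu1": chain_draws[:, :, 0],
        "mu2": chain_draws[:, :, 1],
        "sigma1": np.exp(chain_draws[:, :, 2]),
        "sigma2": np.exp(chain_draws[:, :, 3]),
        "rho": np.tanh(chain_draws[:, :, 4]),
    }
    draws["pi"] = (
        1.0 / (1.0 + np.exp(-chain_draws[:, :, 5]))
        if zi
        else np.zeros_like(chain_draws[:, :, 0])
    )
    rhat = {}
    for name in PARAM_NAMES:
        arr = draws[name]
        if config.n_chains >= 2 and n_kept >= 4:
            try:
                rhat[name] = gelman_rubin(arr)
            except ValueError:
                rhat[name] = np.nan  # constant parameter (e.g. pi in Poisson fit)
        else:
            rhat[name] = np.nan
    return PosteriorSamples(
        feature_id=data.feature_id,
        draws=draws,
        rhat=rhat,
        accept_rate=float(np.mean(accept_rates)),
        n_divergent=n_divergent,
        zero_inflated=zi,
        latent=latent,
    )


def _fit_one(args) -> PosteriorSamples:
    data, hyper, config, seed, index = args
    try:
        return fit_feature(data, hyper, config, seed=(seed, index))
    except Exception as exc:  # recorded, not fatal (independence across features)
        return PosteriorSamples(
            feature_id=data.feature_id,
            draws={},
            rhat={},
            accept_rate=np.nan,
            n_divergent=0,
            zero_inflated=config.zero_inflated,
            error=str(exc),
        )


def fit_all(
    dataset: Sequence[FeatureData],
    hyper: Hyperparams | None = None,
    config: McmcConfig | None = None,
    n_workers: int = 1,
    progress: bool = False,
) -> list[PosteriorSamples]:
    """Fit every feature independently; identical to sequential calls.

    Per-feature seeds derive from ``(config.seed, feature_index)`` so the
    result does not depend on ``n_workers`` or execution order.  Individual
    failures are recorded on the returned object (``error`` field) rather
    than aborting the run.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    hyper = hyper or Hyperparams()
    config = config or McmcConfig()
    jobs = [
        (data, hyper, config, config.seed, index)
        for index, data in enumerate(dataset)
    ]
    if n_workers <= 1:
        results = []
        iterator: Iterable = jobs
        if progress:
            from tqdm import tqdm  # local import: optional dependency at runtime

            iterator = tqdm(jobs, desc="fitting features")
        for job in iterator:
            results.append(_fit_one(job))
        return results
    with ProcessPoolExecutor(max_workers=n_workers) as pool:
        return list(pool.map(_fit_one, jobs, chunksize=4))


def summarize_posteriors(posteriors: Sequence[PosteriorSamples]) -> pd.DataFrame:
    """Posterior summary table: mean/median/sd/q05/q95/rhat per parameter."""
    rows = []
    for post in posteriors:
        row: dict[str, object] = {"feature_id": post.feature_id}
        if post.error is not None:
            row["error"] = post.error
            rows.append(row)
            continue
        row["error"] = ""
        for name in PARAM_NAMES:
            flat = post.stacked(name)
            row[f"{name}_mean"] = np.mean(flat)
            row[f"{name}_median"] = np.median(flat)
            row[f"{name}_sd"] = np.std(flat, ddof=1)
            row[f"{name}_q05"] = np.quantile(flat, 0.05)
            row[f"{name}_q95"] = np.quantile(flat, 0.95)
            row[f"{name}_rhat"] = post.rhat.get(name, np.nan)
        row["accept_rate"] = post.accept_rate
        row["n_divergent"] = post.n_divergent
        rows.append(row)
    return pd.DataFrame(rows)
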