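"""Posterior-probability decision rule with expected-FDR calibration.

A feature is called significant when the posterior probability that its
latent correlation exceeds a minimum threshold ``gamma`` in absolute value,
``p_j(gamma) = P(|rho_j| >= gamma)``, is at least a probability cutoff
``alpha``.  ``gamma`` is either fixed or matched to a quantile of
negative-control posterior estimates, and ``alpha`` is chosen by grid
search so the expected false discovery rate

    EFDR(alpha) = sum_j (1 - p_j) 1{p_j >= alpha} / sum_j 1{p_j >= alpha}

stays at or below a target (default 10%).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorSamples

__all__ = [
    "DecisionConfig",
    "DecisionResult",
    "tail_prob",
    "choose_gamma",
    "efdr",
    "calibrate_alpha",
    "decide",
]


@dataclass(frozen=True)
class DecisionConfig:
    gamma: float | str = "auto"
    target_efdr: float = 0.10
    gamma_quantile: float = 0.90
    alpha_grid_step: float = 0.001
    estimate: str = "median"  # negative-control point estimate of |rho|

    def __post_init__(self) -> None:
        if not 0.0 < self.target_efdr < 1.0:
            raise ValueError("target_efdr must lie in (0, 1)")
        if self.gamma != "auto" and not 0.0 < float(self.gamma) < 1.0:
            raise ValueError("fixed gamma must lie in (0, 1)")
        if self.alpha_grid_step <= 0:
            raise ValueError("alpha_grid_step must be positive")
        if self.estimate not in ("median", "mean"):
            raise ValueError("estimate must be 'median' or 'mean'")


@dataclass
class DecisionResult:
    feature_ids: list[str]
    tail_probs: np.ndarray
    significant: np.ndarray
    gamma: float
    alpha: float
    achieved_efdr: float

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    def to_frame(self, rho_medians: Sequence[float] | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "tail_prob": self.tail_probs,
                "significant": self.significant.astype(int),
            }
        )
        if rho_medians is not None:
            frame.insert(1, "posterior_median_rho", list(rho_medians))
        return frame

    def metadata(self) -> dict:
        return {
            "gamma": self.gamma,
            "alpha": self.alpha,
            "achieved_efdr": self.achieved_efdr,
            "n_significant": self.n_significant,
            "n_features": len(self.feature_ids),
        }

    def write(self, calls_path, metadata_path=None) -> None:
        self.to_frame().to_csv(calls_path, sep="\t", index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def tail_prob(rho_draws: np.ndarray, gamma: float) -> float:
    """Monte-Carlo estimate of P(|rho| >= gamma) from posterior draws."""
    draws = np.asarray(rho_draws, dtype=np.float64).reshape(-1)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    return float(np.mean(np.abs(draws) >= gamma))


def choose_gamma(
    negctrl_abs_rho_estimates: Sequence[float], quantile: float = 0.90
) -> float:
    """Nearest-rank (>=) quantile of negative-control |rho| point estimates."""
    values = np.sort(np.asarray(negctrl_abs_rho_estimates, dtype=np.float64))
    if values.size == 0:
        raise ValueError("no negative-control estimates supplied")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    rank = max(1, math.ceil(quantile * values.size))
    return float(values[rank - 1])


def efdr(tail_probs: Sequence[float], alpha: float) -> float:
    """Expected false discovery rate at probability cutoff ``alpha``.

    Returns 0 when no feature passes the cutoff (empty-set convention).
    """
    p = np.asarray(tail_probs, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("tail probabilities must lie in [0, 1]")
    passed = p >= alpha
    if not np.any(passed):
        return 0.0
    return float(np.sum((1.0 - p)[passed]) / np.sum(passed))


def calibrate_alpha(
    tail_probs: Sequence[float],
    target_efdr: float = 0.10,
    grid_step: float = 0.001,
) -> float:
    """Smallest grid ``alpha`` whose (nonempty) EFDR meets the target.

    Scanning from small alpha maximizes discoveries subject to EFDR
    control.  If no grid point achieves the target with at least one
    discovery, returns 1.0 with a warning (zero discoveries).
    """
    p = np.asarray(tail_probs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty tail-probability vector")
    n_steps = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    for alpha in grid:
        if not np.any(p >= alpha):
            continue
        if efdr(p, alpha) <= target_efdr + 1e-9:  # guard float round-off
            return float(alpha)
    warnings.warn(
        "no probability cutoff satisfies the EFDR target with a nonempty "
        "discovery set; returning alpha=1 (zero discoveries)",
        stacklevel=2,
    )
    return 1.0


def _abs_rho_estimate(post: PosteriorSamples, estimate: str) -> float:
    abs_rho = np.abs(post.stacked("rho"))
    return float(np.median(abs_rho) if estimate == "median" else np.mean(abs_rho))


def decide(
    posteriors: Sequence[PosteriorSamples],
    negctrl_posteriors: Sequence[PosteriorSamples] | None = None,
    config: DecisionConfig | None = None,
) -> DecisionResult:
    """Assemble gamma, alpha and per-feature significance calls."""
    config = config or DecisionConfig()
    posteriors = [p for p in posteriors if p.error is None]
    if len(posteriors) == 0:
        raise ValueError("no successful posterior fits supplied")
    if config.gamma == "auto":
        if not negctrl_posteriors:
            raise ValueError(
                "gamma='auto' requires negative-control posterior fits"
            )
        estimates = [
            _abs_rho_estimate(p, config.estimate)
            for p in negctrl_posteriors
            if p.error is None
        ]
        gamma = choose_gamma(estimates, config.gamma_quantile)
        gamma = float(np.clip(gamma, 1e-6, 1 - 1e-6))
    else:
        gamma = float(config.gamma)
    probs = np.array([tail_prob(p.stacked("rho"), gamma) for p in posteriors])
    alpha = calibrate_alpha(probs, config.target_efdr, config.alpha_grid_step)
    significant = probs >= alpha
    return DecisionResult(
        feature_ids=[p.feature_id for p in posteriors],
        tail_probs=probs,
        significant=significant,
        gamma=gamma,
        alpha=alpha,
        achieved_efdr=efdr(probs, alpha),
    )
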