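"""Synthetic dataset generation from the generative model.

Defaults follow the benchmark design: 300 features x 60 cells, latent
moments mu = (4, 1) and sigma = (3, 2), 20% expression zero inflation,
coverage drawn uniformly on [50, 500] (mean 275), and per-feature latent
correlations drawn from a Beta(15, 15) rescaled to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import FeatureData, FeatureParams

__all__ = [
    "SimConfig",
    "generate_dataset",
    "generate_with_external_latents",
    "make_negative_control",
    "truth_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation design parameters (defaults reproduce the benchmark grid)."""

    n_cells: int = 60
    n_features: int = 300
    mu1: float = 4.0
    mu2: float = 1.0
    sigma1: float = 3.0
    sigma2: float = 2.0
    pi: float = 0.20
    coverage_low: int = 50
    coverage_high: int = 500
    rho_source: str | Sequence[float] = "beta"  # "beta" | "uniform" | explicit
    rho_beta_shape: tuple[float, float] = (15.0, 15.0)
    rho_uniform_range: tuple[float, float] = (-0.8, -0.6)
    s: Sequence[float] | None = None  # cell scaling factors; None -> all ones
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_features < 1:
            raise ValueError("need at least 2 cells and 1 feature")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if not 0 <= self.coverage_low <= self.coverage_high:
            raise ValueError("need 0 <= coverage_low <= coverage_high")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("latent standard deviations must be positive")
        if isinstance(self.rho_source, str) and self.rho_source not in (
            "beta",
            "uniform",
        ):
            raise ValueError("rho_source must be 'beta', 'uniform' or explicit values")

    def coverage_mean(self) -> float:
        """Mean of the inclusive discrete-uniform coverage distribution."""
        return (self.coverage_low + self.coverage_high) / 2.0

    def scaling_factors(self) -> np.ndarray:
        if self.s is None:
            return np.ones(self.n_cells)
        s = np.asarray(self.s, dtype=np.float64)
        if s.shape != (self.n_cells,) or np.any(s <= 0):
            raise ValueError("s must be positive with one entry per cell")
        return s


def _draw_rhos(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.rho_source, str):
        if config.rho_source == "beta":
            d1, d2 = config.rho_beta_shape
            return 2.0 * rng.beta(d1, d2, config.n_features) - 1.0
        lo, hi = config.rho_uniform_range
        return rng.uniform(lo, hi, config.n_features)
    rhos = np.asarray(config.rho_source, dtype=np.float64)
    if rhos.shape != (config.n_features,):
        raise ValueError("explicit rho values must have one entry per feature")
    if np.any(np.abs(rhos) >= 1.0):
        raise ValueError("explicit rho values must lie in (-1, 1)")
    return rhos


def _emit_feature(
    index: int,
    rho: float,
    latent: np.ndarray,
    config: SimConfig,
    s: np.ndarray,
    rng: np.random.Generator,
) -> tuple[FeatureData, FeatureParams, np.ndarray]:
    """Apply both observation noise layers to a latent matrix."""
    I = config.n_cells
    rate = s * np.exp(np.clip(latent[:, 0], None, 500.0))
    counts = rng.poisson(rate)
    dropout = rng.random(I) < config.pi
    y1 = np.where(dropout, 0, counts)
    n = rng.integers(config.coverage_low, config.coverage_high + 1, I)
    y2 = rng.binomial(n, ndtr(latent[:, 1]))
    data = FeatureData(f"feature_{index:04d}", y1, y2, n, s)
    params = FeatureParams(
        mu1=config.mu1,
        mu2=config.mu2,
        sigma1=config.sigma1,
        sigma2=config.sigma2,
        rho=rho,
        pi=config.pi,
        X=latent,
        dropout=dropout,
    )
    return data, params, dropout


def generate_dataset(
    config: SimConfig | None = None,
) -> tuple[list[FeatureData], list[FeatureParams]]:
    """Draw a dataset plus the generating per-feature parameters.

    Per feature: draw rho, draw the I x 2 latent matrix from the bivariate
    Gaussian, draw coverage from the inclusive discrete uniform, then emit
    observed counts through the two noise layers.  Fully reproducible from
    ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    s = config.scaling_factors()
    rhos = _draw_rhos(config, rng)
    dataset: list[FeatureData] = []
    truths: list[FeatureParams] = []
    for j, rho in enumerate(rhos):
        z = rng.standard_normal((config.n_cells, 2))
        x1 = config.mu1 + config.sigma1 * z[:, 0]
        x2 = config.mu2 + config.sigma2 * (
            rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
        )
        latent = np.column_stack([x1, x2])
        data, params, _ = _emit_feature(j, float(rho), latent, config, s, rng)
        dataset.append(data)
        truths.append(params)
    return dataset, truths


def generate_with_external_latents(
    latent_matrix: np.ndarray,
    config: SimConfig | None = None,
    latent_matrix2: np.ndarray | None = None,
) -> tuple[list[FeatureData], list[FeatureParams]]:
    """Generate data with externally supplied expression-layer latents.

    ``latent_matrix`` has shape (I, J): one latent expression value per cell
    and feature (a model-mismatch scenario, e.g. means from an external
    auto-encoder).  The second layer is drawn from its conditional Gaussian
    given the supplied values unless ``latent_matrix2`` is also given.
    """
    config = config or SimConfig()
    X1 = np.asarray(latent_matrix, dtype=np.float64)
    if X1.shape != (config.n_cells, config.n_features):
        raise ValueError(
            f"latent matrix shape {X1.shape} does not match "
            f"(I, J) = ({config.n_cells}, {config.n_features})"
        )
    if latent_matrix2 is not None:
        X2 = np.asarray(latent_matrix2, dtype=np.float64)
        if X2.shape != X1.shape:
            raise ValueError("latent matrices must have identical shapes")
    rng = np.random.default_rng(config.seed)
    s = config.scaling_factors()
    rhos = _draw_rhos(config, rng)
    dataset: list[FeatureData] = []
    truths: list[FeatureParams] = []
    for j, rho in enumerate(rhos):
        x1 = X1[:, j]
        if latent_matrix2 is None:
            # conditional of the second coordinate given the first
            z1 = (x1 - config.mu1) / config.sigma1
            x2 = config.mu2 + config.sigma2 * (
                rho * z1
                + np.sqrt(1.0 - rho**2) * rng.standard_normal(config.n_cells)
            )
        else:
            x2 = X2[:, j]
        latent = np.column_stack([x1, x2])
        data, params, _ = _emit_feature(j, float(rho), latent, config, s, rng)
        dataset.append(data)
        truths.append(params)
    return dataset, truths


def make_negative_control(
    dataset: Sequence[FeatureData], seed: int = 0
) -> list[FeatureData]:
    """Independently permute cells within each layer of every feature.

    Destroys any cross-layer association while preserving each layer's
    marginal multiset exactly; the (y2, n) pair always travels together.
    """
    rng = np.random.default_rng(seed)
    out: list[FeatureData] = []
    for data in dataset:
        order1 = rng.permutation(data.n_cells)
        order2 = rng.permutation(data.n_cells)
        out.append(
            FeatureData(
                feature_id=data.feature_id,
                y1=data.y1[order1],
                y2=data.y2[order2],
                n=data.n[order2],
                s=data.s[order1],  # the expression offset travels with y1
            )
        )
    return out


def truth_table(truths: Sequence[FeatureParams], ids: Sequence[str]) -> pd.DataFrame:
    """Ground-truth parameters as a tidy frame (one row per feature)."""
    return pd.DataFrame(
        {
            "feature_id": list(ids),
            "mu1": [t.mu1 for t in truths],
            "mu2": [t.mu2 for t in truths],
            "sigma1": [t.sigma1 for t in truths],
            "sigma2": [t.sigma2 for t in truths],
            "rho": [t.rho for t in truths],
            "pi": [t.pi for t in truths],
        }
    )
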