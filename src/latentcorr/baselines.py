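"""Frequentist comparator: Pearson/Spearman correlation with BH control.

Expression counts are offset-normalized and log-transformed with a
pseudocount; the epigenome layer is normalized by coverage.  Cells without
coverage are dropped pairwise.  Significance uses a Fisher-z test of the
interval null ``|r| <= u`` (u = 0 reduces to the standard two-sided test),
followed by Benjamini-Hochberg adjustment across features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import FeatureData

__all__ = [
    "BaselineConfig",
    "normalize_for_baseline",
    "correlate",
    "correlation_test",
    "bh_adjust",
    "run_baseline",
]


@dataclass(frozen=True)
class BaselineConfig:
    u: float = 0.0  # interval-null threshold on |r|
    fdr: float = 0.10
    pseudocount: float = 1.0
    method: str = "pearson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.u < 1.0:
            raise ValueError("u must lie in [0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")


def normalize_for_baseline(
    data: FeatureData, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-cell (log(pseudocount + y1/s), y2/n) pairs; n == 0 cells dropped."""
    keep = data.n > 0
    if not np.any(keep):
        raise ValueError(
            f"feature {data.feature_id!r} has no cells with coverage"
        )
    expr = np.log(pseudocount + data.y1[keep] / data.s[keep])
    meth = data.y2[keep] / data.n[keep]
    return np.column_stack([expr, meth])


def correlate(pairs: np.ndarray, method: str = "pearson") -> float:
    """Sample correlation of the paired columns.

    Spearman is Pearson on midranks; ties receive average ranks.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of pairs")
    if pairs.shape[0] < 3:
        raise ValueError("need at least 3 complete pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a coordinate")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def correlation_test(r: float, n_obs: int, u: float = 0.0) -> float:
    """Fisher-z p-value for the interval null ``|r| <= u``.

    ``z = atanh(r)``, ``se = 1/sqrt(n_obs - 3)``,
    ``p = P(|Z| >= (|z| - atanh(u)) / se)``; p = 1 whenever ``|r| <= u``.
    """
    if n_obs < 4:
        raise ValueError("need at least 4 observations")
    if not 0.0 <= u < 1.0:
        raise ValueError("u must lie in [0, 1)")
    if abs(r) >= 1.0:
        return 0.0
    if abs(r) <= u:
        return 1.0
    se = 1.0 / np.sqrt(n_obs - 3)
    stat = (np.abs(np.arctanh(r)) - np.arctanh(u)) / se
    return float(2.0 * stats.norm.sf(stat))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_baseline(
    dataset: Sequence[FeatureData], config: BaselineConfig | None = None
) -> pd.DataFrame:
    """Correlation, p, BH q and significance call for every feature.

    Features where the correlation is undefined (zero variance, too few
    covered cells) get NaN statistics and are excluded from BH adjustment.
    """
    config = config or BaselineConfig()
    rows = []
    for data in dataset:
        row: dict[str, object] = {"feature_id": data.feature_id}
        try:
            pairs = normalize_for_baseline(data, config.pseudocount)
            for method in ("pearson", "spearman"):
                r = correlate(pairs, method)
                row[f"r_{method}"] = r
                row[f"p_{method}"] = correlation_test(
                    r, pairs.shape[0], config.u
                )
        except ValueError:
            row.update(
                r_pearson=np.nan, p_pearson=np.nan,
                r_spearman=np.nan, p_spearman=np.nan,
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    for method in ("pearson", "spearman"):
        q = np.full(len(frame), np.nan)
        ok = frame[f"p_{method}"].notna().to_numpy()
        if ok.any():
            q[ok] = bh_adjust(frame.loc[ok, f"p_{method}"].to_numpy())
        frame[f"q_{method}"] = q
        frame[f"significant_{method}"] = (q <= config.fdr).astype(int)
    return frame
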