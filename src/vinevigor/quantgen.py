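"""Broad-sense heritability, block-adjusted genotype means and trait correlations.

Two estimators of broad-sense heritability H² are provided for a randomized
complete 2-block field design with a replicated control variety:

- the control-based estimator, usable when only one block carries clean data:
  H² = (σ_t² − σ_e²) / σ_t², where σ_t² is the variance over the progeny
  genotypes in the block and σ_e² the variance among the replicated control
  plots (which, being a single genotype, expose pure environmental variance);

- the ANOVA estimator for two complete blocks:
  σ_g² = (MS_genotype − MS_error) / r with r blocks, σ_e² = MS_error, and
  H² = σ_g² / (σ_g² + σ_e²).

All sample variances use the n − 1 denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class VarianceDecomposition:
    sigma_g2: float
    sigma_e2: float
    sigma_t2: float
    H2: float
    estimator: str  # "control" | "anova"
    clamped: bool = False
    #: the unclamped estimate; use this when averaging over replicate
    #: simulations, since truncation at [0, 1] biases the mean
    H2_raw: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma_e2 < 0 or self.sigma_t2 < 0:
            raise ValueError("variances must be non-negative")
        if self.H2_raw is None:
            self.H2_raw = self.H2


def _clamp_h2(h2: float) -> tuple[float, bool]:
    if 0.0 <= h2 <= 1.0:
        return h2, False
    return float(np.clip(h2, 0.0, 1.0)), True


def control_heritability_from_variances(
    sigma_t2: float, sigma_e2: float
) -> VarianceDecomposition:
    """H² = (σ_t² − σ_e²)/σ_t² from precomputed progeny and control variances."""
    if sigma_t2 <= 0:
        raise ValueError("total progeny variance must be positive")
    if sigma_e2 < 0:
        raise ValueError("control variance must be non-negative")
    raw = (sigma_t2 - sigma_e2) / sigma_t2
    h2, clamped = _clamp_h2(raw)
    if clamped:
        warnings.warn(f"H2 estimate clamped to [0, 1] (raw {raw:.3f})")
    return VarianceDecomposition(max(sigma_t2 - sigma_e2, 0.0), sigma_e2,
                                 sigma_t2, h2, "control", clamped, H2_raw=raw)


def control_heritability(progeny_values, control_values) -> VarianceDecomposition:
    """Control-based H² from per-genotype progeny means and control-plot means."""
    prog = np.asarray(progeny_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if len(prog) < 2:
        raise ValueError("need at least 2 progeny genotypes")
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control plots")
    return control_heritability_from_variances(
        float(np.var(prog, ddof=1)), float(np.var(ctrl, ddof=1)))


def _plot_means(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """One value per genotype x block (plant observations averaged per plot)."""
    return (table.groupby(["genotype", "block"], sort=False)[value_col]
            .mean().reset_index())


def anova_heritability(table: pd.DataFrame,
                       value_col: str = "value") -> VarianceDecomposition:
    """ANOVA-based H² from a phenotype table with >= 2 complete blocks.

    The replicate unit is the genotype x block plot mean.  For a balanced
    complete layout the two-way additive sums of squares are computed in
    closed form; an unbalanced table falls back to a least-squares fit of
    genotype + block effects with a warning.
    """
    df = _plot_means(table, value_col)
    blocks = sorted(df["block"].unique())
    r = len(blocks)
    if r < 2:
        raise ValueError("ANOVA estimator needs at least 2 blocks")
    counts = df.pivot_table(index="genotype", columns="block",
                            values=value_col, aggfunc="count")
    balanced = counts.notna().all(axis=None) and (counts == 1).all(axis=None)
    genotypes = df["genotype"].unique()
    g = len(genotypes)
    if balanced:
        wide = df.pivot(index="genotype", columns="block", values=value_col)
        y = wide.to_numpy(float)
        grand = y.mean()
        ss_gen = r * float(np.sum((y.mean(axis=1) - grand) ** 2))
        ss_block = g * float(np.sum((y.mean(axis=0) - grand) ** 2))
        ss_tot = float(np.sum((y - grand) ** 2))
        ss_err = max(ss_tot - ss_gen - ss_block, 0.0)
        df_err = (g - 1) * (r - 1)
    else:
        warnings.warn("unbalanced design; fitting genotype + block by least squares")
        y = df[value_col].to_numpy(float)
        Xg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Xb = pd.get_dummies(df["block"]).to_numpy(float)[:, 1:]
        X = np.hstack([Xg, Xb])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_err = float(np.sum(resid**2))
        # genotype SS adjusted for blocks
        Xr = np.hstack([np.ones((len(y), 1)), Xb])
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        ss_gen = float(np.sum((y - Xr @ br) ** 2)) - ss_err
        df_err = len(y) - (g - 1) - (r - 1) - 1
    ms_gen = ss_gen / (g - 1)
    ms_err = ss_err / max(df_err, 1)
    sigma_e2 = ms_err
    sigma_g2_raw = (ms_gen - ms_err) / r
    sigma_g2 = max(sigma_g2_raw, 0.0)
    denom = sigma_g2 + sigma_e2
    raw_denom = sigma_g2_raw + sigma_e2
    raw = sigma_g2_raw / raw_denom if raw_denom > 0 else 0.0
    h2, clamped = _clamp_h2(sigma_g2 / denom) if denom > 0 else (0.0, True)
    return VarianceDecomposition(sigma_g2, sigma_e2, sigma_g2 + sigma_e2, h2,
                                 "anova", clamped, H2_raw=raw)


def block_adjusted_means(table: pd.DataFrame, value_col: str = "value",
                         shrink: bool = True) -> pd.Series:
    """Per-genotype means with block effects removed (BLUP-style shrinkage).

    Block effects estimated from the two-way layout are subtracted before
    averaging; with ``shrink=True`` the resulting genotype deviations are
    shrunk toward the grand mean by σ_g²/(σ_g² + σ_e²/r), the best linear
    unbiased predictor under the fitted additive model.  Single-block data
    yield plain genotype means.
    """
    df = _plot_means(table, value_col)
    blocks = sorted(df["block"].unique())
    if len(blocks) < 2:
        return df.groupby("genotype", sort=False)[value_col].mean()
    # block effects referenced to the first block, so the adjusted means are
    # invariant to additive offsets applied to the other blocks
    block_means = df.groupby("block")[value_col].mean()
    block_eff = block_means - block_means.loc[blocks[0]]
    adj = df[value_col] - df["block"].map(block_eff)
    means = adj.groupby(df["genotype"], sort=False).mean()
    if not shrink:
        return means
    vc = anova_heritability(table, value_col)
    r = len(blocks)
    denom = vc.sigma_g2 + vc.sigma_e2 / r
    factor = vc.sigma_g2 / denom if denom > 0 else 0.0
    grand = means.mean()
    return grand + (means - grand) * factor


def trait_correlation(x: pd.Series, y: pd.Series) -> float:
    """Squared Pearson correlation (R²) over genotypes present in both series."""
    if not isinstance(x, pd.Series):
        x = pd.Series(x)
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y), index=x.index)
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired genotypes")
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("R^2 undefined for a zero-variance trait")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r
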