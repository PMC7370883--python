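"""Chromosome-wide allelic-imbalance signal.

For each cell-chromosome with sufficient coverage we compute the
min-allele ratio: the minimum of reference/alternate supporting reads at
each embryo-level heterozygous SNP, summed over the chromosome, divided
by the chromosome's total allele-supporting reads. The ratio lies in
[0, 0.5]; 0.5 means perfectly balanced biallelic expression and 0 means
fully monoallelic (the monosomy/haploidy limit). Trisomy (2:1 dosage)
also pulls the ratio below its disomic baseline, so increased imbalance
always means a smaller ratio.

Because the observed ratio correlates with sequencing depth, depth is
regressed out (OLS on log10 total reads, pooled across the data set).
The null distribution of the residuals is estimated robustly from the
interquartile range under the assumption that most cell-chromosomes are
disomic: points between Q1 and Q3 are treated as null, mu_null is their
mean and sigma_null = IQR / (2 * PHI^-1(0.75)). One-sided (lower-tail)
p-values follow, since aneuploidy decreases the residual ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
PHI_INV_75 = float(stats.norm.ppf(0.75))  # ~0.674490


@dataclass
class AINullModel:
    """Depth-regression coefficients plus robust null moments."""

    intercept: float
    slope: float
    mu_null: float
    sigma_null: float
    iqr: float
    degenerate_depth: bool = False  # all depths equal; residual = ratio - mean


def chromosome_ai_ratio(allelic: pd.DataFrame,
                        min_reads: int = 20,
                        min_snps: int = 5) -> pd.DataFrame:
    """Aggregate per-SNP allele counts to per-cell-chromosome ratios.

    ``allelic`` needs columns cell_id, chromosome, refCount, altCount.
    Combinations with < ``min_reads`` total reads or < ``min_snps`` SNPs
    are dropped (logged). Returns (cell_id, chromosome, n_snps,
    total_reads, ai_ratio).
    """
    df = allelic.copy()
    df["_min"] = np.minimum(df["refCount"], df["altCount"])
    df["_tot"] = df["refCount"] + df["altCount"]
    grouped = df.groupby(["cell_id", "chromosome"], sort=True).agg(
        n_snps=("_tot", "size"),
        total_reads=("_tot", "sum"),
        min_sum=("_min", "sum"),
    ).reset_index()
    keep = (grouped["total_reads"] >= min_reads) & (grouped["n_snps"] >= min_snps)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d under-covered cell-chromosome combinations", n_drop)
    out = grouped[keep].copy()
    out["ai_ratio"] = out["min_sum"] / out["total_reads"]
    return out.drop(columns="min_sum").reset_index(drop=True)


def residualize_depth(obs: pd.DataFrame, min_obs: int = 30) -> tuple[pd.DataFrame, AINullModel]:
    """Regress the ratio on log10 depth (pooled OLS) and attach residuals.

    With a degenerate design (all depths equal) residuals are the
    mean-centered ratios. The returned null model has regression
    coefficients filled in; its null moments are fitted separately by
    :func:`fit_null`.
    """
    if len(obs) < min_obs:
        raise ValueError(f"need >= {min_obs} observations to residualize depth, "
                         f"got {len(obs)}")
    obs = obs.copy()
    x = np.log10(obs["total_reads"].to_numpy(float))
    y = obs["ai_ratio"].to_numpy(float)
    if np.ptp(x) == 0:
        warnings.warn("all depths equal; residuals are mean-centered ratios")
        obs["residual"] = y - y.mean()
        model = AINullModel(intercept=y.mean(), slope=0.0, mu_null=np.nan,
                            sigma_null=np.nan, iqr=np.nan, degenerate_depth=True)
        return obs, model
    fit = stats.linregress(x, y)
    obs["residual"] = y - (fit.intercept + fit.slope * x)
    model = AINullModel(intercept=float(fit.intercept), slope=float(fit.slope),
                        mu_null=np.nan, sigma_null=np.nan, iqr=np.nan)
    return obs, model


def fit_null(residuals: np.ndarray, model: AINullModel | None = None,
             min_n: int = 30) -> AINullModel:
    """Estimate null mean/SD of the residuals from their interquartile range.

    Null points are those between Q1 and Q3 (type-7 quantiles); mu_null is
    their mean and sigma_null = IQR / (2 * PHI^-1(0.75)).
    """
    residuals = np.asarray(residuals, float)
    if len(residuals) < min_n:
        raise ValueError(f"need >= {min_n} residuals to fit the null, "
                         f"got {len(residuals)}")
    q1, q3 = np.quantile(residuals, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("degenerate null: residual IQR is zero")
    sigma = iqr / (2.0 * PHI_INV_75)
    mu = float(residuals[(residuals >= q1) & (residuals <= q3)].mean())
    if model is None:
        model = AINullModel(intercept=0.0, slope=0.0, mu_null=mu,
                            sigma_null=sigma, iqr=iqr)
    else:
        model.mu_null, model.sigma_null, model.iqr = mu, float(sigma), float(iqr)
    return model


def ai_pvalues(obs: pd.DataFrame, null: AINullModel) -> pd.DataFrame:
    """Attach Z-scores and one-sided (lower-tail) p-values.

    Increased imbalance means a smaller min-allele ratio, hence the lower
    normal tail P(Z <= z_ai).
    """
    obs = obs.copy()
    z = (obs["residual"].to_numpy(float) - null.mu_null) / null.sigma_null
    obs["z_ai"] = z
    obs["p_ai"] = np.clip(stats.norm.cdf(z), P_FLOOR, 1.0)
    return obs


def allelic_signal(allelic: pd.DataFrame,
                   min_reads: int = 20,
                   min_snps: int = 5) -> tuple[pd.DataFrame, AINullModel]:
    """Full allelic pipeline: ratios -> depth residuals -> null -> p-values."""
    obs = chromosome_ai_ratio(allelic, min_reads=min_reads, min_snps=min_snps)
    obs, model = residualize_depth(obs)
    model = fit_null(obs["residual"].to_numpy(), model)
    return ai_pvalues(obs, model), model
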