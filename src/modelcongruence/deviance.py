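"""Congruence deviance statistics.

Genome-wide scores standardize a model's projection against the robust
center/scale (median, scaled MAD) of the target tumor cohort's projections;
gene-level scores do the same per gene, and pathway scores take the
geometric mean of absolute gene scores over the pathway's DE genes.
Smaller scores mean higher congruence; large p-values signal congruence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data_io import ExpressionMatrix

__all__ = [
    "MAD_CONSTANT",
    "RobustCenterScale",
    "DevianceRecord",
    "robust_center_scale",
    "ds_sda",
    "ds_pvalue",
    "bootstrap_ci",
    "ds_gene",
    "ds_gene_matrix",
    "ds_path",
    "ds_path_pvalue",
    "tumor_pathway_null",
]

#: MAD scaling for consistency with the normal standard deviation.
MAD_CONSTANT = 1.4826


class DegenerateScaleError(ValueError):
    """Raised when a robust scale estimate is exactly zero."""


@dataclass
class RobustCenterScale:
    mu_hat: float
    s_hat: float
    sigma_hat: float
    n: int
    degenerate: bool = False

    def require_valid(self) -> None:
        if self.degenerate or self.s_hat <= 0:
            raise DegenerateScaleError("robust scale is zero (all values identical?)")


def robust_center_scale(tumor_proj: np.ndarray, mad_constant: float = MAD_CONSTANT,
                        sigma_policy: str = "mad") -> RobustCenterScale:
    """Median and scaled-MAD of the target-class tumor projections.

    ``sigma_policy`` selects the dispersion used for the normal-tail
    p-value: ``"mad"`` reuses the scaled MAD (default), ``"sd"`` uses the
    sample standard deviation.
    """
    t = np.asarray(tumor_proj, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 tumor projections")
    mu = float(np.median(t))
    s = float(mad_constant * np.median(np.abs(t - mu)))
    if sigma_policy == "mad":
        sigma = s
    elif sigma_policy == "sd":
        sigma = float(np.std(t, ddof=1))
    else:
        raise ValueError(f"unknown sigma_policy {sigma_policy!r}")
    return RobustCenterScale(mu_hat=mu, s_hat=s, sigma_hat=sigma, n=t.size,
                             degenerate=(s == 0.0))


@dataclass
class DevianceRecord:
    model_id: str
    class_k: str
    ds_sda: float
    signed_distance: float
    ci_low: float
    ci_high: float
    pval: float
    p_sda: float


def ds_sda(c_i: float, rcs: RobustCenterScale) -> float:
    """Absolute robust standardized distance |c_i - mu| / s."""
    rcs.require_valid()
    return abs(c_i - rcs.mu_hat) / rcs.s_hat


def ds_pvalue(c_i: float, rcs: RobustCenterScale) -> float:
    """Two-sided normal-tail p-value of the model projection under the
    tumor cohort's (mu, sigma)."""
    rcs.require_valid()
    if rcs.sigma_hat <= 0:
        raise DegenerateScaleError("sigma_hat is zero")
    z = abs(c_i - rcs.mu_hat) / rcs.sigma_hat
    return float(2.0 * norm.sf(z))


def bootstrap_ci(c_i: float, tumor_proj: np.ndarray, b: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 mad_constant: float = MAD_CONSTANT,
                 return_replicates: bool = False):
    """Ordinary-bootstrap percentile CI for the deviance score on the log2
    scale, back-transformed.

    Replicates with a zero MAD or a zero score (log undefined) are dropped
    with a logged count.
    """
    t = np.asarray(tumor_proj, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 tumor projections")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, t.size, size=(b, t.size))
    samples = t[idx]
    mu = np.median(samples, axis=1)
    s = mad_constant * np.median(np.abs(samples - mu[:, None]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = np.abs(c_i - mu) / s
    ok = np.isfinite(ds) & (ds > 0)
    n_dropped = int(b - ok.sum())
    if n_dropped:
        warnings.warn(f"bootstrap_ci: dropped {n_dropped} degenerate replicates")
    if not ok.any():
        raise DegenerateScaleError("all bootstrap replicates degenerate")
    log_ds = np.log2(ds[ok])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(log_ds, [alpha, 1.0 - alpha])
    ci = (float(2.0 ** lo), float(2.0 ** hi))
    if return_replicates:
        return ci, ds[ok]
    return ci


def ds_gene(model_value: float, tumor_values: np.ndarray,
            mad_constant: float = MAD_CONSTANT) -> float:
    """Signed per-gene deviance (c - median) / scaled-MAD; NaN when the
    tumor MAD is zero."""
    t = np.asarray(tumor_values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 tumor values")
    mu = np.median(t)
    sigma = mad_constant * np.median(np.abs(t - mu))
    if sigma == 0.0:
        return float("nan")
    return float((model_value - mu) / sigma)


def ds_gene_matrix(models: ExpressionMatrix, tumor: ExpressionMatrix,
                   mad_constant: float = MAD_CONSTANT) -> np.ndarray:
    """Vectorized signed DS_gene for every (gene, model); genes must match.

    Returns a genes x models array with NaN where the tumor MAD is zero.
    """
    if models.gene_ids != tumor.gene_ids:
        raise ValueError("gene lists must match (use intersect_genes first)")
    t = tumor.values
    mu = np.median(t, axis=1)
    sigma = mad_constant * np.median(np.abs(t - mu[:, None]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (models.values - mu[:, None]) / sigma[:, None]
    out[sigma == 0.0, :] = np.nan
    return out


def ds_path(gene_devs: np.ndarray) -> float:
    """Geometric mean of |DS_gene| over a pathway's usable genes.

    NaN entries (zero-MAD genes) are excluded with a warning; an exact
    zero |DS_gene| propagates to a zero pathway score.
    """
    d = np.abs(np.asarray(gene_devs, dtype=float))
    n_nan = int(np.isnan(d).sum())
    if n_nan:
        warnings.warn(f"ds_path: excluding {n_nan} undefined gene deviances")
        d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no usable gene deviances for pathway score")
    if (d == 0.0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(d))))


def ds_path_pvalue(observed: float, tumor_ds_path: np.ndarray) -> float:
    """One-sided empirical p with the add-one estimator; small p means the
    model deviates more than the tumor null (worse congruence)."""
    nulls = np.asarray(tumor_ds_path, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise ValueError("empty tumor null vector")
    return float((1.0 + np.sum(nulls >= observed)) / (1.0 + nulls.size))


def tumor_pathway_null(tumor: ExpressionMatrix, pathway_genes: list[str],
                       mad_constant: float = MAD_CONSTANT) -> np.ndarray:
    """Leave-one-out null distribution of the pathway score over the
    target-class tumor samples.

    Each tumor sample is scored against the median/MAD computed from the
    remaining samples, avoiding self-bias.
    """
    sub = tumor.subset_genes([g for g in pathway_genes if g in set(tumor.gene_ids)])
    v = sub.values  # genes x samples
    n = v.shape[1]
    if n < 4:
        raise ValueError("need at least 4 tumor samples for the LOO null")
    out = np.empty(n)
    for j in range(n):
        rest = np.delete(v, j, axis=1)
        mu = np.median(rest, axis=1)
        sigma = mad_constant * np.median(np.abs(rest - mu[:, None]), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = (v[:, j] - mu) / sigma
        dev[sigma == 0.0] = np.nan
        usable = np.abs(dev[~np.isnan(dev)])
        if usable.size == 0:
            out[j] = np.nan
            continue
        out[j] = 0.0 if (usable == 0.0).any() else float(np.exp(np.mean(np.log(usable))))
    return out
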