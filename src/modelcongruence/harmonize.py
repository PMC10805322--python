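"""Tumor-vs-model expression harmonization.

Three interchangeable correctors are provided: quantile normalization,
parametric empirical-Bayes batch correction, and a two-step aligner that
removes top contrastive principal components and then applies a mutual
nearest neighbor shift to the model samples (tumor space is the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .data_io import ExpressionMatrix

__all__ = [
    "HarmonizationConfig",
    "quantile_normalize",
    "eb_batch_correct",
    "cpca_mnn_align",
    "harmonize",
]


@dataclass
class HarmonizationConfig:
    method: str = "none"  # none | quantile | eb_batch | cpca_mnn
    n_cpc_remove: int = 4
    mnn_k: int = 5
    #: number of MNN correction passes; a large batch vector biases the
    #: first pairing along the offset direction, a second pass re-pairs in
    #: the nearly-aligned space and removes the residual
    mnn_iter: int = 2
    cpca_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpc_remove < 0:
            raise ValueError("n_cpc_remove must be >= 0")
        if self.mnn_k < 1:
            raise ValueError("mnn_k must be >= 1")
        if self.cpca_alpha < 0:
            raise ValueError("cpca_alpha must be >= 0")


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean distribution of order
    statistics; ties within a column receive the mean of their target
    quantile values."""
    if x.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return x
    v = x.values
    reference = np.sort(v, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        ranks = rankdata(v[:, j], method="average")  # 1-based, ties averaged
        # fractional ranks interpolate between adjacent reference values
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return ExpressionMatrix(
        gene_ids=list(x.gene_ids), sample_ids=list(x.sample_ids),
        values=out, scale=x.scale,
        provenance={**x.provenance, "harmonize": "quantile"},
    )


def eb_batch_correct(x: ExpressionMatrix, batch: list[str]) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch correction.

    Per-gene batch effects are estimated, shrunk towards common priors
    (normal prior for additive effects, inverse-gamma for multiplicative),
    and removed.  The non-parametric variant is not implemented.
    """
    batch = np.asarray([str(b) for b in batch])
    if len(batch) != x.n_samples:
        raise ValueError("batch labels length mismatch")
    levels, inverse = np.unique(batch, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("eb_batch_correct requires >= 2 batches")
    counts = np.bincount(inverse)
    if (counts < 2).any():
        small = levels[counts < 2].tolist()
        raise ValueError(f"batches with < 2 samples: {small}")

    v = x.values  # genes x samples
    G, N = v.shape
    B = len(levels)
    nb = counts.astype(float)

    # grand mean weighted by batch size; pooled variance after removing
    # batch means
    batch_mean = np.stack([v[:, inverse == b].mean(axis=1) for b in range(B)], axis=1)
    grand = batch_mean @ (nb / N)
    resid = v - batch_mean[:, inverse]
    pooled_var = (resid ** 2).sum(axis=1) / N
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))

    z = (v - grand[:, None]) / pooled_sd[:, None]

    # per-batch location/scale on standardized data
    gamma_hat = np.stack([z[:, inverse == b].mean(axis=1) for b in range(B)], axis=1)
    delta_hat = np.stack([z[:, inverse == b].var(axis=1, ddof=1) for b in range(B)], axis=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    # method-of-moments EB hyperpriors per batch
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    # inverse-gamma prior (lambda shape, theta scale) by moment matching
    lam = (2 * d_var + d_mean ** 2) / np.maximum(d_var, 1e-12)
    theta = (d_mean * d_var + d_mean ** 3) / np.maximum(d_var, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(B):
        g, d = gamma_hat[:, b].copy(), delta_hat[:, b].copy()
        for _ in range(100):
            g_new = (nb[b] * tau2[b] * gamma_hat[:, b] + d * gamma_bar[b]) / (
                nb[b] * tau2[b] + d)
            zb = z[:, inverse == b]
            sse = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[b] + 0.5 * sse) / (nb[b] / 2 + lam[b] - 1)
            d_new = np.maximum(d_new, 1e-12)
            if np.max(np.abs(g_new - g)) < 1e-6 and np.max(np.abs(d_new - d)) < 1e-6:
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[:, b], delta_star[:, b] = g, d

    adj = (z - gamma_star[:, inverse]) / np.sqrt(delta_star[:, inverse])
    out = adj * pooled_sd[:, None] + grand[:, None]
    return ExpressionMatrix(
        gene_ids=list(x.gene_ids), sample_ids=list(x.sample_ids),
        values=out, scale=x.scale,
        provenance={**x.provenance, "harmonize": "eb_batch"},
    )


def _contrastive_directions(a: np.ndarray, b: np.ndarray, alpha: float,
                            n_dir: int) -> np.ndarray:
    """Top eigenvectors of Cov(a) - alpha * Cov(b); rows of a/b are samples."""
    ca = np.cov(a, rowvar=False)
    cb = np.cov(b, rowvar=False)
    m = ca - alpha * cb
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    return v[:, order[:n_dir]]


def cpca_mnn_align(tumor: ExpressionMatrix, model: ExpressionMatrix,
                   cfg: HarmonizationConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two-step alignment.

    Step 1 residualizes both matrices against the top ``n_cpc_remove``
    contrastive covariance directions computed in each direction
    (tumor-vs-model and model-vs-tumor).  Step 2 finds mutual nearest
    neighbor pairs between the residualized sample clouds and subtracts a
    locally smoothed batch vector from each model sample, moving models
    toward tumor space.
    """
    if tumor.gene_ids != model.gene_ids:
        raise ValueError("inputs must be gene-intersected with identical gene order")
    if tumor.n_samples <= cfg.n_cpc_remove or model.n_samples <= cfg.n_cpc_remove:
        raise ValueError("need more samples than n_cpc_remove in each matrix")

    t = tumor.values.T.copy()  # samples x genes
    m = model.values.T.copy()

    if cfg.n_cpc_remove > 0:
        dirs = np.concatenate([
            _contrastive_directions(t, m, cfg.cpca_alpha, cfg.n_cpc_remove),
            _contrastive_directions(m, t, cfg.cpca_alpha, cfg.n_cpc_remove),
        ], axis=1)
        q, _ = np.linalg.qr(dirs)
        for arr in (t, m):
            center = arr.mean(axis=0)
            centered = arr - center
            arr -= centered @ q @ q.T

    warn_no_pairs = False
    for _ in range(max(cfg.mnn_iter, 1)):
        pairs = _mutual_nearest_pairs(t, m, cfg.mnn_k)
        if pairs.size == 0:
            warnings.warn("cpca_mnn_align: no mutual nearest neighbor pairs "
                          "found; returning cPCA-residualized matrices")
            warn_no_pairs = True
            break
        ti, mi = pairs[:, 0], pairs[:, 1]
        corrections = t[ti] - m[mi]  # vectors moving model points to tumor space
        anchors = m[mi]
        d2 = cdist(m, anchors, metric="sqeuclidean")
        # Gaussian smoothing bandwidth set by the reference (tumor) cloud's
        # neighbor spacing: model samples closer than one tumor spacing
        # share essentially the same batch vector, so a tight model cluster
        # is translated rigidly instead of collapsing onto its neighbors
        tt = cdist(t, t, metric="sqeuclidean")
        k_local = min(cfg.mnn_k, tt.shape[1] - 1)
        sigma2 = float(np.mean(np.sort(tt, axis=1)[:, 1:k_local + 1])) + 1e-12
        w = np.exp(-d2 / (2 * sigma2))
        w /= w.sum(axis=1, keepdims=True)
        m = m + w @ corrections
        # re-pair only while a global batch vector dominates the
        # correction field; balanced local corrections mean we are done
        global_shift = np.linalg.norm(corrections.mean(axis=0))
        rms = np.sqrt(np.mean(np.sum(corrections ** 2, axis=1)))
        if global_shift < 0.5 * rms:
            break

    prov = {"harmonize": "cpca_mnn", "n_cpc_remove": cfg.n_cpc_remove,
            "mnn_k": cfg.mnn_k, "cpca_alpha": cfg.cpca_alpha,
            "no_mnn_pairs": warn_no_pairs}
    t_out = ExpressionMatrix(gene_ids=list(tumor.gene_ids),
                             sample_ids=list(tumor.sample_ids),
                             values=t.T, scale=tumor.scale,
                             provenance={**tumor.provenance, **prov})
    m_out = ExpressionMatrix(gene_ids=list(model.gene_ids),
                             sample_ids=list(model.sample_ids),
                             values=m.T, scale=model.scale,
                             provenance={**model.provenance, **prov})
    return t_out, m_out


def _mutual_nearest_pairs(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """(i, j) index pairs where a[i] is among b[j]'s k nearest in a and
    vice versa; rows are samples."""
    d = cdist(a, b)
    k_ab = min(k, d.shape[1])
    k_ba = min(k, d.shape[0])
    nn_ab = np.argsort(d, axis=1)[:, :k_ab]  # for each a, nearest b's
    nn_ba = np.argsort(d, axis=0)[:k_ba, :]  # for each b, nearest a's
    ba_sets = [set(nn_ba[:, j]) for j in range(d.shape[1])]
    pairs = [(i, j) for i in range(d.shape[0]) for j in nn_ab[i]
             if i in ba_sets[j]]
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def harmonize(tumor: ExpressionMatrix, model: ExpressionMatrix,
              cfg: HarmonizationConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Dispatch to the configured method, recording provenance."""
    if cfg.method == "none":
        return tumor, model
    if cfg.method == "quantile":
        joint = ExpressionMatrix(
            gene_ids=list(tumor.gene_ids),
            sample_ids=list(tumor.sample_ids) + list(model.sample_ids),
            values=np.concatenate([tumor.values, model.values], axis=1),
            scale=tumor.scale,
        )
        normed = quantile_normalize(joint)
        t = normed.subset_samples(list(tumor.sample_ids))
        m = normed.subset_samples(list(model.sample_ids))
        return t, m
    if cfg.method == "eb_batch":
        joint = ExpressionMatrix(
            gene_ids=list(tumor.gene_ids),
            sample_ids=list(tumor.sample_ids) + list(model.sample_ids),
            values=np.concatenate([tumor.values, model.values], axis=1),
            scale=tumor.scale,
        )
        batch = ["tumor"] * tumor.n_samples + ["model"] * model.n_samples
        corrected = eb_batch_correct(joint, batch)
        return (corrected.subset_samples(list(tumor.sample_ids)),
                corrected.subset_samples(list(model.sample_ids)))
    if cfg.method == "cpca_mnn":
        return cpca_mnn_align(tumor, model, cfg)
    raise ValueError(f"unknown harmonization method {cfg.method!r}")
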