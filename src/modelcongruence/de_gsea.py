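"""Differential expression between tumor subtypes and preranked GSEA.

The default DE backend is a per-gene Welch test on log2 expression; a
simplified single-factor negative-binomial Wald test handles raw counts.
Externally computed DE tables (gene, log2fc, pval, adj_pval columns) can be
injected downstream, so exact equivalence with heavier DE machinery is not
required here.

GSEA is the preranked weighted Kolmogorov-Smirnov statistic with a
gene-set-resampling null, add-one empirical p-values and sign-matched NES
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, GeneSetCollection, SampleAnnotation

__all__ = [
    "DEResult",
    "EnrichmentResult",
    "differential_expression",
    "de_results_to_frame",
    "de_results_from_frame",
    "enrichment_score",
    "preranked_gsea",
    "filter_pathways",
]

LOG2_FC_DEFAULT = 1.5
ALPHA_DEFAULT = 0.05


@dataclass
class DEResult:
    gene: str
    log2fc: float
    pval: float
    adj_pval: float
    is_de: bool


@dataclass
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    pval: float
    adj_pval: float
    size: int
    n_de: int = 0
    pinned: bool = False


def differential_expression(tumor: ExpressionMatrix, labels: list[SampleAnnotation],
                            target: str, method: str = "welch_log",
                            fc_threshold: float = LOG2_FC_DEFAULT,
                            alpha: float = ALPHA_DEFAULT) -> list[DEResult]:
    """Per-gene two-sided DE test of target vs comparison tumor samples.

    A gene is flagged DE when |fold change| > ``fc_threshold`` (natural
    scale) and BH-adjusted p < ``alpha``.
    """
    ann = {a.sample_id: a for a in labels}
    labs = np.array([ann[s].class_label for s in tumor.sample_ids])
    classes = np.unique(labs)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    if target not in classes:
        raise ValueError(f"target {target!r} not among {classes.tolist()}")
    mask = labs == target
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each class needs >= 3 samples for DE testing")

    if method == "welch_log":
        a = tumor.values[:, mask]
        b = tumor.values[:, ~mask]
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    elif method == "nb_wald":
        if tumor.scale != "counts":
            raise ValueError("nb_wald requires a counts matrix")
        log2fc, pvals = _nb_wald(tumor.values, mask)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    adj = multipletests(pvals, method="fdr_bh")[1]
    log2_thresh = np.log2(fc_threshold)
    out = []
    for g, fc, p, q in zip(tumor.gene_ids, log2fc, pvals, adj):
        out.append(DEResult(gene=g, log2fc=float(fc), pval=float(p),
                            adj_pval=float(q),
                            is_de=bool(abs(fc) > log2_thresh and q < alpha)))
    return out


def _nb_wald(counts: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Simplified negative-binomial Wald test: per-gene GLM with a single
    group factor, log link, method-of-moments dispersion, library-size
    offsets from the median-of-ratios."""
    import statsmodels.api as sm

    size = _median_of_ratios(counts)
    design = np.column_stack([np.ones(counts.shape[1]), mask.astype(float)])
    offset = np.log(size)
    log2fc = np.empty(counts.shape[0])
    pvals = np.empty(counts.shape[0])
    for i, y in enumerate(counts):
        norm_y = y / size
        mu = norm_y.mean()
        var = norm_y.var(ddof=1)
        disp = max((var - mu) / mu ** 2, 1e-8) if mu > 0 else 1e-8
        try:
            fam = sm.families.NegativeBinomial(alpha=disp)
            res = sm.GLM(y, design, family=fam, offset=offset).fit()
            coef = res.params[1]
            se = res.bse[1]
            log2fc[i] = coef / np.log(2.0)
            pvals[i] = 2.0 * stats.norm.sf(abs(coef / se)) if se > 0 else 1.0
        except Exception:  # all-zero or degenerate gene
            log2fc[i] = 0.0
            pvals[i] = 1.0
    return log2fc, pvals


def _median_of_ratios(counts: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc.mean(axis=1)
    finite = np.isfinite(ref)
    if not finite.any():
        return np.ones(counts.shape[1])
    ratios = logc[finite, :] - ref[finite, None]
    return np.exp(np.median(ratios, axis=0))


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def de_results_from_frame(df: pd.DataFrame, fc_threshold: float = LOG2_FC_DEFAULT,
                          alpha: float = ALPHA_DEFAULT) -> list[DEResult]:
    """Build DEResult records from an external table with columns
    gene, log2fc, pval, adj_pval (is_de recomputed from the thresholds)."""
    need = {"gene", "log2fc", "pval", "adj_pval"}
    if not need.issubset(df.columns):
        raise ValueError(f"external DE table must have columns {sorted(need)}")
    log2_thresh = np.log2(fc_threshold)
    return [DEResult(gene=str(r.gene), log2fc=float(r.log2fc),
                     pval=float(r.pval), adj_pval=float(r.adj_pval),
                     is_de=bool(abs(r.log2fc) > log2_thresh and r.adj_pval < alpha))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# preranked GSEA


def enrichment_score(order_stats: np.ndarray, member_mask: np.ndarray,
                     weight_p: float = 1.0) -> float:
    """Weighted KS enrichment score on a pre-sorted (descending) rank list.

    ``order_stats`` are the rank metric values in descending order and
    ``member_mask`` marks pathway members at those positions.  weight_p=0
    reduces to the classical unweighted KS statistic.
    """
    n = len(order_stats)
    n_hit = int(member_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("pathway must be a proper subset of the ranked universe")
    w = np.abs(order_stats) ** weight_p
    hit_w = np.where(member_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = member_mask.astype(float)
        total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~member_mask) / (n - n_hit)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def preranked_gsea(ranks: dict[str, float], sets: GeneSetCollection,
                   n_perm: int = 10000, weight_p: float = 1.0, seed: int = 0,
                   min_size: int = 1) -> list[EnrichmentResult]:
    """Preranked GSEA with a random-gene-set null.

    For each pathway, ``n_perm`` same-size random gene sets are drawn from
    the ranked universe; the two-sided empirical p-value is the add-one
    fraction of null |ES| at least as extreme, and NES divides ES by the
    mean |null ES| of matching sign.  BH adjustment is applied across
    pathways.
    """
    if not ranks:
        raise ValueError("empty rank mapping")
    genes = np.array(list(ranks.keys()))
    values = np.array([ranks[g] for g in genes], dtype=float)
    order = np.argsort(-values, kind="stable")
    # null sets are drawn by gene identity (original order), so rank
    # negation flips every ES — observed and null — exactly
    orig_to_sorted = np.empty(len(genes), dtype=int)
    orig_to_sorted[order] = np.arange(len(genes))
    genes, values = genes[order], values[order]
    pos_of = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    rng = np.random.default_rng(seed)
    results = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        in_univ = [g for g in members if g in pos_of]
        size = len(in_univ)
        if size < min_size or size == 0:
            continue
        if size >= n:
            raise ValueError(f"pathway {name!r} spans the whole ranked universe")
        mask = np.zeros(n, dtype=bool)
        mask[[pos_of[g] for g in in_univ]] = True
        es = enrichment_score(values, mask, weight_p)

        if size not in null_cache:
            null = np.empty(n_perm)
            m = np.zeros(n, dtype=bool)
            for b in range(n_perm):
                m[:] = False
                m[orig_to_sorted[rng.choice(n, size=size, replace=False)]] = True
                null[b] = enrichment_score(values, m, weight_p)
            null_cache[size] = null
        null = null_cache[size]

        pval = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
        nes = es / denom if denom > 0 else 0.0
        results.append(EnrichmentResult(pathway=name, es=es, nes=float(nes),
                                        pval=float(pval), adj_pval=float("nan"),
                                        size=size))
    if results:
        adj = multipletests([r.pval for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.adj_pval = float(q)
    return results


def filter_pathways(enr: list[EnrichmentResult], de: list[DEResult],
                    sets: GeneSetCollection, min_de: int = 20,
                    size_low: int = 30, size_high: int = 200,
                    nes_abs: float = 1.5,
                    pinned: list[str] | None = None) -> tuple[list[str], list[str]]:
    """Split pathways into an analysis set (enough DE genes) and a stricter
    selection set (size window and |NES| bound); pinned pathways are
    appended to the selection set regardless.

    All bounds are strict inequalities.  Annotates each EnrichmentResult
    with its DE-gene count and pinned flag in place.
    """
    de_genes = {r.gene for r in de if r.is_de}
    pinned = list(pinned or [])
    analysis, selection = [], []
    for r in enr:
        members = sets.get(r.pathway, frozenset())
        r.n_de = len(members & de_genes)
        if r.n_de > min_de:
            analysis.append(r.pathway)
            if size_low < r.size < size_high and abs(r.nes) > nes_abs:
                selection.append(r.pathway)
    for name in pinned:
        hit = next((r for r in enr if r.pathway == name), None)
        if hit is None:
            warnings.warn(f"pinned pathway {name!r} not in enrichment results")
            continue
        hit.pinned = True
        if name not in selection:
            selection.append(name)
    return analysis, selection
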