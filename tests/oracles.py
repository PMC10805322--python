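"""Independent straight-line oracles used to cross-check the package.

Everything here is deliberately written with plain loops and textbook
formulas, sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dense_lda_direction(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Classical two-class LDA direction: pooled-covariance inverse times
    the class-mean difference.  x is samples x features, y boolean."""
    a, b = x[y], x[~y]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sa = (a - ma).T @ (a - ma)
    sb = (b - mb).T @ (b - mb)
    pooled = (sa + sb) / (len(x) - 2)
    return np.linalg.solve(pooled, ma - mb)


def median_(vals) -> float:
    s = sorted(vals)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def scaled_mad(vals, constant: float = 1.4826) -> float:
    m = median_(vals)
    return constant * median_([abs(v - m) for v in vals])


def ds_sda_oracle(c: float, tumor_proj) -> float:
    return abs(c - median_(tumor_proj)) / scaled_mad(tumor_proj)


def ds_gene_oracle(model_value: float, tumor_values) -> float:
    sigma = scaled_mad(tumor_values)
    return (model_value - median_(tumor_values)) / sigma


def ds_path_oracle(gene_devs) -> float:
    logs = [math.log(abs(d)) for d in gene_devs]
    return math.exp(sum(logs) / len(logs))


def unweighted_ks_es(ordered_members: list[bool]) -> float:
    """Classical KS enrichment statistic on a descending-ranked list."""
    n = len(ordered_members)
    n_hit = sum(ordered_members)
    n_miss = n - n_hit
    best, p_hit, p_miss = 0.0, 0.0, 0.0
    for is_member in ordered_members:
        if is_member:
            p_hit += 1.0 / n_hit
        else:
            p_miss += 1.0 / n_miss
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


def weighted_ks_es(values_desc, members: list[bool], weight_p: float) -> float:
    """Weighted KS statistic matching the GSEA definition, plain loops."""
    n = len(values_desc)
    n_hit = sum(members)
    wsum = sum(abs(v) ** weight_p for v, m in zip(values_desc, members) if m)
    best, p_hit, p_miss = 0.0, 0.0, 0.0
    for v, m in zip(values_desc, members):
        if m:
            p_hit += (abs(v) ** weight_p) / wsum
        else:
            p_miss += 1.0 / (n - n_hit)
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


def exhaustive_gsea_pvalue(values_desc, members: list[bool],
                           weight_p: float = 1.0) -> float:
    """Exact two-sided enrichment p by enumerating every same-size subset
    of the ranked universe (no add-one, the population probability)."""
    n = len(values_desc)
    size = sum(members)
    observed = weighted_ks_es(values_desc, members, weight_p)
    n_extreme = 0
    total = 0
    for combo in itertools.combinations(range(n), size):
        mask = [i in combo for i in range(n)]
        es = weighted_ks_es(values_desc, mask, weight_p)
        if abs(es) >= abs(observed) - 1e-12:
            n_extreme += 1
        total += 1
    return n_extreme / total


def bh_adjust(pvals) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * n / rank_from_end)
        adj[i] = val
        prev = val
    return adj
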