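"""Sparse discriminant analysis by optimal scoring for a binary contrast.

The solver alternates between (a) an elastic-net regression of the scored
class indicator on the standardized gene matrix and (b) the constrained
optimal-score update, which for the binary case has the closed form
``theta ~ D^{-1} Y' X beta`` rescaled onto the constraint sphere
``(1/n) theta' Y'Y theta = 1``.  Both half-steps are exact minimizers, so
the penalized objective is non-increasing across iterations.

A one-dimensional Gaussian LDA fitted on the projected tumor samples
supplies posterior assignment probabilities for the target class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq
from scipy.special import expit
from sklearn.linear_model import ElasticNet, Lasso, lars_path

from .data_io import ExpressionMatrix, SampleAnnotation

__all__ = ["SDAModel", "Projection", "fit_sda", "project",
           "assignment_probability", "cv_tune"]


@dataclass
class Projection:
    sample_id: str
    value: float
    source: str = "model"


@dataclass
class SDAModel:
    gene_ids: list[str]
    beta: np.ndarray
    theta: np.ndarray
    gamma: float
    lam: float | int
    center: np.ndarray
    scale_: np.ndarray
    class_names: tuple[str, str]  # (target, comparison)
    lda1d: dict = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, b in zip(self.gene_ids, self.beta) if b != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "class_names": list(self.class_names),
            "gamma": self.gamma,
            "lam": self.lam,
            "theta": self.theta.tolist(),
            "genes": self.gene_ids,
            "beta": self.beta.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale_.tolist(),
            "lda1d": self.lda1d,
            "n_iter": self.n_iter,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SDAModel":
        with open(path, "rt", encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            gene_ids=p["genes"], beta=np.asarray(p["beta"]),
            theta=np.asarray(p["theta"]), gamma=p["gamma"], lam=p["lam"],
            center=np.asarray(p["center"]), scale_=np.asarray(p["scale"]),
            class_names=tuple(p["class_names"]), lda1d=p["lda1d"],
            n_iter=p["n_iter"],
        )


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


def _indicator(labels: list[str], class_names: tuple[str, str]) -> np.ndarray:
    y = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        y[i, 0 if lab == class_names[0] else 1] = 1.0
    return y


def _enet_beta(x: np.ndarray, y: np.ndarray, gamma: float, lam: float | int) -> np.ndarray:
    """Minimize ||y - X b||^2 + gamma ||b||^2 + lam ||b||_1.

    ``lam`` given as an int is a sparsity bound: the LARS elastic-net path
    (on ridge-augmented data) is followed until at most ``lam`` predictors
    are active.
    """
    n, g = x.shape
    if gamma > 0:
        x_aug = np.vstack([x, np.sqrt(gamma) * np.eye(g)])
        y_aug = np.concatenate([y, np.zeros(g)])
    else:
        x_aug, y_aug = x, y

    if isinstance(lam, (int, np.integer)) and not isinstance(lam, bool):
        nnz = int(lam)
        _, _, coefs = lars_path(x_aug, y_aug, method="lasso", max_iter=8 * nnz + 32)
        active = np.count_nonzero(coefs, axis=0)
        ok = np.where(active <= nnz)[0]
        return coefs[:, ok[-1]] if len(ok) else coefs[:, 0]

    lam = float(lam)
    if lam == 0.0:
        if gamma > 0:
            return np.linalg.solve(x.T @ x + gamma * np.eye(g), x.T @ y)
        return lstsq(x, y)[0]
    # sklearn objective: (1/2n)||y-Xb||^2 + a*l1*||b||_1 + (a/2)(1-l1)||b||^2
    alpha = lam / (2 * n) + gamma / n
    l1_ratio = (lam / (2 * n)) / alpha
    est = (Lasso if gamma == 0 else ElasticNet)(
        alpha=alpha, fit_intercept=False, max_iter=50000, tol=1e-10,
        **({} if gamma == 0 else {"l1_ratio": l1_ratio}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)
    return est.coef_.copy()


def _objective(x, y_ind, theta, beta, gamma, lam) -> float:
    fit = y_ind @ theta - x @ beta
    l1 = float(lam) if not isinstance(lam, (int, np.integer)) else 0.0
    return float(fit @ fit + gamma * beta @ beta + l1 * np.abs(beta).sum())


def fit_sda(x: ExpressionMatrix, labels: list[SampleAnnotation], target: str,
            gamma: float = 1e-3, lam_or_nnz: float | int = 0.0,
            max_iter: int = 100, tol: float = 1e-7, seed: int = 0,
            priors: str = "proportional") -> SDAModel:
    """Fit the binary sparse discriminant model on tumor training data.

    Genes are centered and unit-variance scaled internally; constant genes
    are dropped with a warning.  ``lam_or_nnz`` is the lasso weight when a
    float, or a nonzero-count bound when an int.
    """
    ann = {a.sample_id: a for a in labels}
    labs = []
    for s in x.sample_ids:
        if s not in ann or ann[s].class_label is None:
            raise ValueError(f"sample {s} lacks a class label")
        labs.append(ann[s].class_label)
    classes = sorted(set(labs))
    if len(classes) != 2:
        raise ValueError(f"exactly two class labels required, got {classes}")
    if target not in classes:
        raise ValueError(f"target {target!r} not among labels {classes}")
    comparison = classes[0] if classes[1] == target else classes[1]
    class_names = (target, comparison)
    counts = {c: labs.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")

    xm = x.values.T.astype(float)  # samples x genes
    center = xm.mean(axis=0)
    sd = xm.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant genes")
    genes = [g for g, k in zip(x.gene_ids, keep) if k]
    center, sd = center[keep], sd[keep]
    xs = (xm[:, keep] - center) / sd

    n = xs.shape[0]
    y_ind = _indicator(labs, class_names)
    d = (y_ind.T @ y_ind) / n  # diagonal of class proportions

    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(2)
    # remove the trivial constant score (D-orthogonality) and normalize
    ones = np.ones(2)
    theta -= ones * (theta @ d @ ones) / (ones @ d @ ones)
    if abs(theta @ d @ theta) < 1e-12:
        theta = np.array([1.0, -1.0])
    theta /= np.sqrt(theta @ d @ theta)

    trace: list[float] = []
    beta = np.zeros(xs.shape[1])
    for it in range(max_iter):
        beta = _enet_beta(xs, y_ind @ theta, gamma, lam_or_nnz)
        # constrained optimal-score update
        proj = y_ind.T @ (xs @ beta)
        theta_new = np.linalg.solve(y_ind.T @ y_ind, proj)
        norm = np.sqrt(max(theta_new @ d @ theta_new, 0.0))
        if norm < 1e-12:
            break  # beta is zero (lam too large); keep current theta
        theta = theta_new / norm
        obj = _objective(xs, y_ind, theta, beta, gamma, lam_or_nnz)
        trace.append(obj)
        if it > 0 and abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            break
    else:
        raise ConvergenceError(
            f"SDA failed to converge in {max_iter} iterations", trace)

    model = SDAModel(
        gene_ids=genes, beta=beta, theta=theta, gamma=gamma, lam=lam_or_nnz,
        center=center, scale_=sd, class_names=class_names,
        objective_trace=trace, n_iter=len(trace),
    )
    tumor_proj = np.array([p.value for p in project(model, x)])
    model.lda1d = _fit_lda1d(tumor_proj, labs, class_names, priors)
    return model


def _fit_lda1d(proj: np.ndarray, labs: list[str],
               class_names: tuple[str, str], priors: str) -> dict:
    t_mask = np.array([lab == class_names[0] for lab in labs])
    m0, m1 = proj[t_mask].mean(), proj[~t_mask].mean()
    n0, n1 = int(t_mask.sum()), int((~t_mask).sum())
    ss = ((proj[t_mask] - m0) ** 2).sum() + ((proj[~t_mask] - m1) ** 2).sum()
    var = ss / (n0 + n1 - 2)
    if priors == "equal":
        p0 = p1 = 0.5
    else:
        p0, p1 = n0 / (n0 + n1), n1 / (n0 + n1)
    return {"mean_target": float(m0), "mean_comparison": float(m1),
            "pooled_var": float(var), "prior_target": float(p0),
            "prior_comparison": float(p1),
            "median_target": float(np.median(proj[t_mask])),
            "median_comparison": float(np.median(proj[~t_mask]))}


def project(model: SDAModel, x: ExpressionMatrix,
            source: str = "model") -> list[Projection]:
    """Project samples onto the discriminant axis using the training
    standardization."""
    missing = [g for g in model.gene_ids if g not in set(x.gene_ids)]
    if missing:
        raise KeyError(f"matrix lacks model genes: {missing[:5]}")
    sub = x.subset_genes(model.gene_ids)
    xs = (sub.values.T - model.center) / model.scale_
    vals = xs @ model.beta
    return [Projection(sample_id=s, value=float(v), source=source)
            for s, v in zip(x.sample_ids, vals)]


def assignment_probability(model: SDAModel, proj: list[Projection]) -> dict[str, float]:
    """Posterior probability of the target class from the 1-D Gaussian LDA."""
    p = model.lda1d
    if not p:
        raise ValueError("model.lda1d not fitted")
    var = p["pooled_var"]
    if var <= 0:
        raise ValueError("degenerate pooled variance in 1-D LDA")
    out = {}
    for pr in proj:
        v = pr.value
        # log-posterior difference target vs comparison
        la = -0.5 * (v - p["mean_target"]) ** 2 / var + np.log(p["prior_target"])
        lb = -0.5 * (v - p["mean_comparison"]) ** 2 / var + np.log(p["prior_comparison"])
        out[pr.sample_id] = float(expit(la - lb))
    return out


def cv_tune(x: ExpressionMatrix, labels: list[SampleAnnotation], target: str,
            gamma_grid: list[float], lam_grid: list[float], folds: int = 5,
            repeats: int = 5, seed: int = 0) -> tuple[float, float, list[dict]]:
    """Repeated stratified k-fold selection of (gamma, lam) by CV accuracy;
    ties broken toward sparser models (larger lam)."""
    if not gamma_grid or not lam_grid:
        raise ValueError("empty tuning grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ann = {a.sample_id: a for a in labels}
    labs = np.array([ann[s].class_label for s in x.sample_ids])
    classes, class_counts = np.unique(labs, return_counts=True)
    if folds > class_counts.min():
        raise ValueError(
            f"folds={folds} exceeds smallest class size {class_counts.min()}")

    rng = np.random.default_rng(seed)
    table: list[dict] = []
    results = {}
    for g in gamma_grid:
        for lam in lam_grid:
            accs = []
            for rep in range(repeats):
                fold_of = np.empty(len(labs), dtype=int)
                for c in classes:
                    idx = np.where(labs == c)[0]
                    idx = rng.permutation(idx)
                    fold_of[idx] = np.arange(len(idx)) % folds
                for f in range(folds):
                    tr = fold_of != f
                    te = ~tr
                    x_tr = x.subset_samples([s for s, m in zip(x.sample_ids, tr) if m])
                    x_te = x.subset_samples([s for s, m in zip(x.sample_ids, te) if m])
                    mdl = fit_sda(x_tr, labels, target, gamma=g, lam_or_nnz=lam,
                                  seed=seed)
                    probs = assignment_probability(mdl, project(mdl, x_te))
                    pred = np.array([probs[s] > 0.5 for s in x_te.sample_ids])
                    truth = labs[te] == target
                    accs.append(float(np.mean(pred == truth)))
            mean_acc = float(np.mean(accs))
            results[(g, lam)] = mean_acc
            table.append({"gamma": g, "lam": lam, "cv_accuracy": mean_acc})
    best = max(results, key=lambda k: (results[k], k[1]))
    return best[0], best[1], table
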