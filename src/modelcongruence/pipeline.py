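"""End-to-end orchestration: harmonize, genome-wide pre-selection,
pathway/gene scoring, ranking, report emission.

Model pre-selection combines the assignment probability and the
deviance-score p-value (both strict inequalities); the final ranking is the
ascending arithmetic mean of pathway deviance scores over the unbiased
selection pathway set (pinned pathways are scored but excluded from the
average), ties broken by the genome-wide deviance then model id.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (ExpressionMatrix, GeneSetCollection, SampleAnnotation,
                      intersect_genes, read_annotations, read_expression,
                      read_gmt)
from .de_gsea import (DEResult, differential_expression, de_results_from_frame,
                      de_results_to_frame, filter_pathways, preranked_gsea)
from .deviance import (DevianceRecord, bootstrap_ci, ds_gene_matrix, ds_path,
                       ds_path_pvalue, ds_pvalue, ds_sda, robust_center_scale,
                       tumor_pathway_null)
from .harmonize import HarmonizationConfig, harmonize
from .sda import assignment_probability, fit_sda, project

__all__ = ["SelectionCriteria", "preselect_models", "score_pathways",
           "rank_models", "run_pipeline", "PathwayDevianceCell"]


@dataclass
class SelectionCriteria:
    p_sda_min: float = 0.5
    ds_pval_min: float = 0.05
    stringent_p_sda_min: float = 0.8
    stringent_ds_pval_min: float = 0.1
    pinned_models: list[str] = field(default_factory=list)
    pinned_pathways: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.p_sda_min, self.ds_pval_min,
                  self.stringent_p_sda_min, self.stringent_ds_pval_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if (self.stringent_p_sda_min < self.p_sda_min
                or self.stringent_ds_pval_min < self.ds_pval_min):
            raise ValueError("stringent thresholds must be >= base thresholds")


@dataclass
class PathwayDevianceCell:
    pathway: str
    model_id: str
    ds_path: float
    pval: float
    n_de_genes: int

    @property
    def pval_glyph(self) -> int:
        """Number of significance circles: p<0.1 -> 1, <0.05 -> 2, <0.01 -> 3."""
        return sum(self.pval < t for t in (0.1, 0.05, 0.01))


def preselect_models(dev: list[DevianceRecord], crit: SelectionCriteria) -> list[dict]:
    """Flag every model against the base and stringent criteria; pinned
    models are always carried forward."""
    out = []
    for r in dev:
        base = r.p_sda > crit.p_sda_min and r.pval > crit.ds_pval_min
        stringent = (r.p_sda > crit.stringent_p_sda_min
                     and r.pval > crit.stringent_ds_pval_min)
        pinned = r.model_id in crit.pinned_models
        out.append({"model_id": r.model_id, "record": r, "base": base,
                    "stringent": stringent, "pinned": pinned,
                    "selected": stringent or pinned})
    return out


def score_pathways(models: ExpressionMatrix, tumor_k: ExpressionMatrix,
                   de: list[DEResult], sets: GeneSetCollection,
                   pathways: list[str],
                   mad_constant: float = 1.4826) -> list[PathwayDevianceCell]:
    """Pathway deviance score and one-sided empirical p-value for every
    (pathway, model) pair, against a leave-one-out tumor null."""
    de_genes = {r.gene for r in de if r.is_de}
    tumor_aligned, models_aligned = intersect_genes(tumor_k, models)
    gene_dev = ds_gene_matrix(models_aligned, tumor_aligned, mad_constant)
    gene_pos = {g: i for i, g in enumerate(tumor_aligned.gene_ids)}

    cells: list[PathwayDevianceCell] = []
    for pname in pathways:
        usable = sorted((sets.get(pname, frozenset()) & de_genes) & set(gene_pos))
        if not usable:
            raise ValueError(f"pathway {pname!r} has no usable DE genes")
        rows = [gene_pos[g] for g in usable]
        null = tumor_pathway_null(tumor_aligned, usable, mad_constant)
        for j, mid in enumerate(models_aligned.sample_ids):
            score = ds_path(gene_dev[rows, j])
            pv = ds_path_pvalue(score, null)
            cells.append(PathwayDevianceCell(pathway=pname, model_id=mid,
                                             ds_path=score, pval=pv,
                                             n_de_genes=len(usable)))
    return cells


def rank_models(cells: list[PathwayDevianceCell], selection_set: list[str],
                dev: list[DevianceRecord]) -> list[dict]:
    """Ascending order of mean pathway deviance over the selection set;
    ties broken by genome-wide deviance then model id."""
    ds_by_model = {r.model_id: r.ds_sda for r in dev}
    per_model: dict[str, dict[str, float]] = {}
    for c in cells:
        per_model.setdefault(c.model_id, {})[c.pathway] = c.ds_path
    ranked = []
    for mid, scores in per_model.items():
        missing = [p for p in selection_set if p not in scores]
        if missing:
            raise ValueError(f"model {mid} missing pathway scores: {missing[:5]}")
        avg = float(np.mean([scores[p] for p in selection_set])) if selection_set else float("nan")
        ranked.append({"model_id": mid, "avg_ds_path": avg,
                       "ds_sda": ds_by_model.get(mid, float("inf"))})
    ranked.sort(key=lambda r: (r["avg_ds_path"], r["ds_sda"], r["model_id"]))
    for i, r in enumerate(ranked, 1):
        r["rank"] = i
    return ranked


# ---------------------------------------------------------------------------
# full pipeline


DEFAULT_CONFIG = {
    "harmonize": {"method": "none", "n_cpc_remove": 4, "mnn_k": 5,
                  "cpca_alpha": 1.0},
    "sda": {"gamma": 1e-3, "lam": 0.0, "max_iter": 100},
    "deviance": {"bootstrap": 1000, "mad_constant": 1.4826,
                 "sigma_policy": "mad", "ci_level": 0.95},
    "de": {"method": "welch_log", "fc_threshold": 1.5, "alpha": 0.05},
    "gsea": {"n_perm": 2000, "weight_p": 1.0, "min_size": 1},
    "selection": {"p_sda_min": 0.5, "ds_pval_min": 0.05,
                  "stringent_p_sda_min": 0.8, "stringent_ds_pval_min": 0.1,
                  "min_de": 20, "size_low": 30, "size_high": 200,
                  "nes_abs": 1.5, "pinned_models": [], "pinned_pathways": [],
                  "stage3": "stringent"},
    "seed": 0,
}


def _merge_config(config: dict) -> dict:
    merged = {k: dict(v) if isinstance(v, dict) else v
              for k, v in DEFAULT_CONFIG.items()}
    for key, val in config.items():
        if key in merged and isinstance(merged[key], dict) and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage={stage}] {cause}")
        self.stage = stage


def run_pipeline(config: dict, tumor: ExpressionMatrix | None = None,
                 models: ExpressionMatrix | None = None,
                 annotations: list[SampleAnnotation] | None = None,
                 sets: GeneSetCollection | None = None,
                 external_de: pd.DataFrame | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the report dictionary.

    Inputs may be passed in memory or referenced by paths in
    ``config["input"]``; ``out_dir`` (or ``config["out_dir"]``) enables
    artifact emission (deviance.tsv, gsea.tsv, pathway_deviance.tsv,
    gene_deviance.tsv, report.json).
    """
    cfg = _merge_config(config)
    seed = int(cfg.get("seed", 0))
    target = cfg.get("target") or cfg.get("input", {}).get("target")
    if target is None:
        raise ValueError("config must declare the target class label")

    stage = "load"
    try:
        inp = cfg.get("input", {})
        if tumor is None:
            tumor = read_expression(inp["tumor"])
        if models is None:
            models = read_expression(inp["models"])
        if annotations is None:
            annotations = read_annotations(inp["annotations"])
        if sets is None:
            sets = read_gmt(inp["gmt"])
        if external_de is None and inp.get("external_de"):
            external_de = pd.read_csv(inp["external_de"], sep="\t")
        tumor, models = intersect_genes(tumor, models)

        stage = "harmonize"
        hcfg = HarmonizationConfig(seed=seed, **{
            k: v for k, v in cfg["harmonize"].items()})
        tumor_h, models_h = harmonize(tumor, models, hcfg)

        stage = "fit_sda"
        ann_by_id = {a.sample_id: a for a in annotations}
        labeled = [s for s in tumor_h.sample_ids
                   if ann_by_id.get(s) and ann_by_id[s].class_label]
        tumor_train = tumor_h.subset_samples(labeled)
        scfg = cfg["sda"]
        model = fit_sda(tumor_train, annotations, target, gamma=scfg["gamma"],
                        lam_or_nnz=scfg["lam"], max_iter=scfg["max_iter"],
                        seed=seed)

        stage = "project"
        tumor_proj = project(model, tumor_train, source="tumor")
        model_proj = project(model, models_h, source="model")
        p_sda = assignment_probability(model, model_proj)
        k_proj = np.array([p.value for p in tumor_proj
                           if ann_by_id[p.sample_id].class_label == target])

        stage = "deviance"
        dcfg = cfg["deviance"]
        rcs = robust_center_scale(k_proj, dcfg["mad_constant"],
                                  dcfg["sigma_policy"])
        records = []
        for i, pr in enumerate(model_proj):
            ci = bootstrap_ci(pr.value, k_proj, b=int(dcfg["bootstrap"]),
                              level=dcfg["ci_level"], seed=seed + i,
                              mad_constant=dcfg["mad_constant"])
            records.append(DevianceRecord(
                model_id=pr.sample_id, class_k=target,
                ds_sda=ds_sda(pr.value, rcs),
                signed_distance=(pr.value - rcs.mu_hat) / rcs.s_hat,
                ci_low=ci[0], ci_high=ci[1],
                pval=ds_pvalue(pr.value, rcs),
                p_sda=p_sda[pr.sample_id]))

        stage = "preselect"
        sel = cfg["selection"]
        crit = SelectionCriteria(
            p_sda_min=sel["p_sda_min"], ds_pval_min=sel["ds_pval_min"],
            stringent_p_sda_min=sel["stringent_p_sda_min"],
            stringent_ds_pval_min=sel["stringent_ds_pval_min"],
            pinned_models=list(sel["pinned_models"]),
            pinned_pathways=list(sel["pinned_pathways"]))
        flags = preselect_models(records, crit)
        gate = "base" if sel.get("stage3") == "base" else "stringent"
        kept = [f["model_id"] for f in flags if f[gate] or f["pinned"]]

        stage = "de"
        decfg = cfg["de"]
        if external_de is not None:
            de = de_results_from_frame(external_de, decfg["fc_threshold"],
                                       decfg["alpha"])
        else:
            de = differential_expression(tumor_train, annotations, target,
                                         method=decfg["method"],
                                         fc_threshold=decfg["fc_threshold"],
                                         alpha=decfg["alpha"])

        stage = "gsea"
        gcfg = cfg["gsea"]
        ranks = {r.gene: r.log2fc for r in de}
        enr = preranked_gsea(ranks, sets.restrict(ranks), n_perm=int(gcfg["n_perm"]),
                             weight_p=gcfg["weight_p"], seed=seed,
                             min_size=int(gcfg["min_size"]))

        stage = "filter_pathways"
        analysis_set, selection_set = filter_pathways(
            enr, de, sets, min_de=sel["min_de"], size_low=sel["size_low"],
            size_high=sel["size_high"], nes_abs=sel["nes_abs"],
            pinned=crit.pinned_pathways)
        unbiased_set = [p for p in selection_set if p not in crit.pinned_pathways]

        stage = "score_pathways"
        warn = None
        cells, ranked = [], []
        if kept and selection_set:
            tumor_k = tumor_train.subset_samples(
                [s for s in tumor_train.sample_ids
                 if ann_by_id[s].class_label == target])
            models_kept = models_h.subset_samples(kept)
            cells = score_pathways(models_kept, tumor_k, de, sets,
                                   selection_set, dcfg["mad_constant"])
            ranked = rank_models(cells, unbiased_set, records)
        elif kept:
            warn = "no pathways passed the selection filters; genome-wide ranking only"
            warnings.warn(warn)
            ranked = [{"model_id": r.model_id, "avg_ds_path": None,
                       "ds_sda": r.ds_sda} for r in records
                      if r.model_id in kept]
            ranked.sort(key=lambda r: (r["ds_sda"], r["model_id"]))
            for i, r in enumerate(ranked, 1):
                r["rank"] = i
        else:
            warn = "no models passed the pre-selection criteria"
            warnings.warn(warn)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    report = {
        "provenance": {"config_hash": _config_hash(cfg), "seed": seed,
                       "version": __version__, "target": target,
                       "harmonize_method": hcfg.method},
        "deviance": [{"model_id": r.model_id, "ds_sda": r.ds_sda,
                      "signed_distance": r.signed_distance,
                      "ci_low": r.ci_low, "ci_high": r.ci_high,
                      "pval": r.pval, "p_sda": r.p_sda} for r in records],
        "preselection": [{k: v for k, v in f.items() if k != "record"}
                         for f in flags],
        "n_de_genes": sum(r.is_de for r in de),
        "gsea": [{"pathway": r.pathway, "nes": r.nes, "pval": r.pval,
                  "adj_pval": r.adj_pval, "size": r.size, "n_de": r.n_de,
                  "pinned": r.pinned} for r in enr],
        "analysis_pathways": analysis_set,
        "selection_pathways": selection_set,
        "pathway_deviance": [{"pathway": c.pathway, "model_id": c.model_id,
                              "ds_path": c.ds_path, "pval": c.pval,
                              "n_de_genes": c.n_de_genes,
                              "glyph": c.pval_glyph} for c in cells],
        "ranking": ranked,
        "warning": warn,
    }

    out = out_dir or cfg.get("out_dir")
    if out is not None:
        _write_artifacts(Path(out), report, de, cells, models_h, tumor_train,
                         ann_by_id, target, dcfg["mad_constant"])
    return report


def _write_artifacts(out: Path, report: dict, de, cells, models_h,
                     tumor_train, ann_by_id, target, mad_constant) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report["deviance"]).to_csv(out / "deviance.tsv", sep="\t",
                                            index=False, float_format="%.10g")
    de_results_to_frame(de).to_csv(out / "de.tsv", sep="\t", index=False,
                                   float_format="%.10g")
    pd.DataFrame(report["gsea"]).to_csv(out / "gsea.tsv", sep="\t",
                                        index=False, float_format="%.10g")
    if cells:
        pd.DataFrame(report["pathway_deviance"]).to_csv(
            out / "pathway_deviance.tsv", sep="\t", index=False,
            float_format="%.10g")
    # gene-level deviance for every model against the target tumor cohort
    tumor_k = tumor_train.subset_samples(
        [s for s in tumor_train.sample_ids
         if ann_by_id[s].class_label == target])
    tk, mk = intersect_genes(tumor_k, models_h)
    gd = ds_gene_matrix(mk, tk, mad_constant)
    pd.DataFrame(gd, index=tk.gene_ids, columns=mk.sample_ids).to_csv(
        out / "gene_deviance.tsv", sep="\t", index_label="gene",
        float_format="%.10g")
    with open(out / "report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
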