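"""Synthetic tumor cohorts and candidate models with planted structure.

The generative model is Gaussian on the log2 scale: two tumor subtypes
separated by ``signature_effect`` on a block of signature genes, and
deterministic candidate models placed at the target-class mean profile,
displaced along the signature axis by a configured distance ``d`` expressed
in robust-scale units of the projected tumor cohort (so the true
genome-wide deviance is known analytically), plus optional per-pathway
discordance offsets and a tumor-vs-model batch offset.

Pathway discordance offsets are applied with alternating sign across the
pathway's genes so that they stay near-invisible to the genome-wide
projection while dominating the pathway-level score — the structure the
two-stage selection is designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, GeneSetCollection, SampleAnnotation

__all__ = ["ScenarioConfig", "ModelSpec", "GroundTruth", "simulate_scenario",
           "default_scenario", "make_worked_fixture"]

TARGET_LABEL = "subtypeA"
OTHER_LABEL = "subtypeB"


@dataclass
class ModelSpec:
    model_id: str
    d: float = 0.0
    pathway_offsets: dict[str, float] = field(default_factory=dict)
    #: sd (in noise_sd units) of random per-gene perturbations on the
    #: signature block — emulates a model from an unrelated population that
    #: can slip past the genome-wide criteria while being mechanistically
    #: discordant
    signature_scramble: float = 0.0


@dataclass
class ScenarioConfig:
    n_tumor_k: int = 150
    n_tumor_other: int = 150
    n_genes: int = 120
    n_signature_genes: int = 48
    signature_effect: float = 1.0
    background_effect_sd: float = 0.15
    noise_sd: float = 0.3
    pathway_spec: dict[str, list[int]] | None = None
    models: list[ModelSpec] = field(default_factory=list)
    batch_offset: float | np.ndarray = 0.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    emit_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if min(self.n_tumor_k, self.n_tumor_other, self.n_genes) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass
class GroundTruth:
    signature_genes: list[str]
    model_d: dict[str, float]
    discordant_pathways: dict[str, list[str]]
    de_genes: list[str]
    class_labels: tuple[str, str] = (TARGET_LABEL, OTHER_LABEL)


def _default_pathways(cfg: ScenarioConfig) -> dict[str, list[int]]:
    """Two pathways of 40 genes: each mixes 24 signature genes with 16
    background genes, exercising the DE-count and size filters."""
    m = cfg.n_signature_genes
    half = m // 2
    bg = list(range(m, cfg.n_genes))
    return {
        "PATH_CORE": list(range(0, half)) + bg[: 40 - half],
        "PATH_AUX": list(range(half, m)) + bg[40 - half: 80 - 2 * half],
    }


def simulate_scenario(cfg: ScenarioConfig) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                                    list[SampleAnnotation],
                                                    GeneSetCollection, GroundTruth]:
    """Generate (tumor, models, annotations, gene sets, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    genes = [f"G{i:04d}" for i in range(G)]
    sig_idx = np.arange(cfg.n_signature_genes)

    baseline = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(G)
    # small heterogeneous true differences on background genes give the
    # fold-change spectrum a realistic graded shape (nearly none pass the
    # DE threshold, but GSEA rank weights are not bimodal)
    bg_diff = np.zeros(G)
    bg_mask = np.ones(G, dtype=bool)
    bg_mask[sig_idx] = False
    bg_diff[bg_mask] = cfg.background_effect_sd * rng.standard_normal(int(bg_mask.sum()))
    mean_k = baseline + bg_diff / 2.0
    mean_k[sig_idx] += cfg.signature_effect
    mean_other = baseline - bg_diff / 2.0

    n_k, n_o = cfg.n_tumor_k, cfg.n_tumor_other
    tumor_vals = np.empty((G, n_k + n_o))
    tumor_vals[:, :n_k] = mean_k[:, None] + cfg.noise_sd * rng.standard_normal((G, n_k))
    tumor_vals[:, n_k:] = mean_other[:, None] + cfg.noise_sd * rng.standard_normal((G, n_o))
    tumor_ids = [f"T{i:04d}" for i in range(n_k + n_o)]
    tumor = ExpressionMatrix(gene_ids=genes, sample_ids=tumor_ids,
                             values=tumor_vals, scale="log2tpm")

    pathway_spec = cfg.pathway_spec or _default_pathways(cfg)
    sets = GeneSetCollection(
        {name: {genes[i] for i in idx} for name, idx in pathway_spec.items()})

    # unit signature axis in raw space; projecting class-k tumors onto it
    # has population sd = noise_sd, so a displacement of d * noise_sd along
    # the axis sits at a true robust-scale distance of d
    u = np.zeros(G)
    u[sig_idx] = 1.0 / np.sqrt(len(sig_idx))

    model_specs = cfg.models or [ModelSpec("M_congruent", 0.0)]
    model_vals = np.empty((G, len(model_specs)))
    discordant: dict[str, list[str]] = {}
    for j, spec in enumerate(model_specs):
        v = mean_k + spec.d * cfg.noise_sd * u
        if spec.signature_scramble > 0:
            v[sig_idx] += (spec.signature_scramble * cfg.noise_sd
                           * rng.standard_normal(len(sig_idx)))
        for pname, off in spec.pathway_offsets.items():
            if pname not in pathway_spec:
                raise ValueError(f"unknown pathway {pname!r} in model {spec.model_id}")
            for rank, gi in enumerate(pathway_spec[pname]):
                v[gi] += ((-1) ** rank) * off * cfg.noise_sd
            if off != 0:
                discordant.setdefault(spec.model_id, []).append(pname)
        model_vals[:, j] = v
    offset = np.asarray(cfg.batch_offset, dtype=float)
    model_vals += (offset[:, None] if offset.ndim == 1 else offset)
    models = ExpressionMatrix(gene_ids=genes,
                              sample_ids=[s.model_id for s in model_specs],
                              values=model_vals, scale="log2tpm")

    ann = [SampleAnnotation(sample_id=s, source="tumor",
                            class_label=TARGET_LABEL if i < n_k else OTHER_LABEL)
           for i, s in enumerate(tumor_ids)]
    ann += [SampleAnnotation(sample_id=s.model_id, source="model")
            for s in model_specs]

    truth = GroundTruth(
        signature_genes=[genes[i] for i in sig_idx],
        model_d={s.model_id: s.d for s in model_specs},
        discordant_pathways=discordant,
        de_genes=[genes[i] for i in sig_idx],
    )
    if cfg.emit_counts:
        counts = ExpressionMatrix(
            gene_ids=genes, sample_ids=tumor_ids,
            values=rng.poisson(2.0 ** tumor_vals).astype(float), scale="counts")
        return tumor, models, ann, sets, truth, counts
    return tumor, models, ann, sets, truth


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """One congruent model (d=0), distractors at d in {1, 2, 3}, and one
    model discordant only in PATH_AUX."""
    return ScenarioConfig(
        n_genes=400,
        models=[
            ModelSpec("M_congruent", 0.0),
            ModelSpec("M_d1", 1.0),
            ModelSpec("M_d2", 2.0),
            ModelSpec("M_d3", 3.0),
            ModelSpec("M_discordant", 0.0, pathway_offsets={"PATH_AUX": 2.5}),
        ],
        seed=seed,
    )


def default_pipeline_config(seed: int = 0, n_perm: int = 1000,
                            bootstrap: int = 1000) -> dict:
    """Pipeline configuration matched to :func:`default_scenario`: a sparse
    fit bounded at 64 nonzero genes keeps the discriminant axis on the
    signature block so planted distances are recovered on scale."""
    return {
        "target": TARGET_LABEL,
        "sda": {"gamma": 1e-3, "lam": 64},
        "gsea": {"n_perm": n_perm},
        "deviance": {"bootstrap": bootstrap},
        "seed": seed,
    }


def make_worked_fixture() -> dict:
    """Tiny fixed bundle (8 genes, 12 tumors, 3 models, 2 pathways) with a
    hand-checkable projection weight vector.

    Values are rounded to 3 decimals so the fixture is stable plain text;
    regeneration is byte-identical.
    """
    rng = np.random.default_rng(20240110)
    genes = [f"g{i}" for i in range(8)]
    tumor_ids = [f"t{i}" for i in range(12)]
    base = np.round(5.0 + rng.standard_normal(8), 3)
    tumor_vals = np.round(base[:, None] + 0.5 * rng.standard_normal((8, 12)), 3)
    tumor = ExpressionMatrix(gene_ids=genes, sample_ids=tumor_ids,
                             values=tumor_vals, scale="log2tpm")

    med = np.median(tumor_vals, axis=1)
    mad = 1.4826 * np.median(np.abs(tumor_vals - med[:, None]), axis=1)
    model_vals = np.column_stack([
        med,                # m_center: at the per-gene tumor median
        med + 2.0 * mad,    # m_plus2: +2 scaled MADs on every gene
        np.round(med + 0.7 * mad * np.array([1, -1, 1, -1, 1, -1, 1, -1]), 6),
    ])
    models = ExpressionMatrix(gene_ids=genes,
                              sample_ids=["m_center", "m_plus2", "m_mixed"],
                              values=model_vals, scale="log2tpm")

    beta = np.array([1.0, -0.5, 0.25, 0.75, -1.0, 0.5, -0.25, 0.1])
    sets = GeneSetCollection({"fixP1": set(genes[:4]), "fixP2": set(genes[4:])})
    ann = [SampleAnnotation(sample_id=t, source="tumor", class_label=TARGET_LABEL)
           for t in tumor_ids]
    ann += [SampleAnnotation(sample_id=m, source="model")
            for m in models.sample_ids]
    return {"tumor": tumor, "models": models, "beta": beta, "sets": sets,
            "annotations": ann}
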