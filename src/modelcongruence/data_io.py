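"""Tabular and gene-set I/O plus the shared validated domain types.

Expression tables are TSV with genes in rows (first column = gene symbol)
and samples in columns, the common GEO/DepMap layout.  Gene identifiers are
treated as opaque symbols; no aliasing or ID mapping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "intersect_genes",
]

SCALES = ("log2tpm", "counts")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression table.

    ``scale`` is ``"log2tpm"`` for continuous log2-scale values or
    ``"counts"`` for non-negative integer read counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2tpm"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if any(not g for g in self.gene_ids):
            raise ValueError("empty gene symbol")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing entries in validated matrix")
        if self.scale == "counts":
            if (self.values < 0).any():
                raise ValueError("counts matrix contains negative entries")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts matrix contains non-integer entries")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "log2tpm", **kw) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index),
            sample_ids=list(df.columns),
            values=df.to_numpy(dtype=float),
            scale=scale,
            **kw,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            scale=self.scale,
            provenance=dict(self.provenance),
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not present: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            values=self.values[:, cols],
            scale=self.scale,
            provenance=dict(self.provenance),
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: origin (tumor vs model) and optional class label."""

    sample_id: str
    source: str  # "tumor" | "model"
    class_label: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("tumor", "model"):
            raise ValueError(f"source must be 'tumor' or 'model', got {self.source!r}")


class GeneSetCollection(dict):
    """Mapping pathway name -> frozenset of gene symbols, with descriptions."""

    def __init__(self, sets: Mapping[str, set] | None = None,
                 descriptions: Mapping[str, str] | None = None):
        super().__init__()
        self.descriptions: dict[str, str] = {}
        if sets:
            for name, genes in sets.items():
                self.add(name, genes, (descriptions or {}).get(name, ""))

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self:
            raise ValueError(f"duplicate pathway name {name!r}")
        genes = frozenset(str(g).strip() for g in genes if str(g).strip())
        if not genes:
            raise ValueError(f"pathway {name!r} is empty")
        super().__setitem__(name, genes)
        self.descriptions[name] = description

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied pathways."""
        universe = set(universe)
        out = GeneSetCollection()
        for name, genes in self.items():
            kept = genes & universe
            if kept:
                out.add(name, kept, self.descriptions.get(name, ""))
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, scale: str = "log2tpm", missing_policy: str = "error",
                    duplicate_policy: str = "error", transpose: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Parameters
    ----------
    missing_policy
        ``"error"`` (default) raises on any missing cell, ``"drop_gene"``
        removes genes with missing entries, ``"zero"`` fills with 0.
    duplicate_policy
        ``"error"`` (default) raises on duplicated gene rows, ``"first"``
        keeps the first occurrence.
    transpose
        Set when the file is laid out samples-in-rows.
    """
    if missing_policy not in ("error", "drop_gene", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in header")
    if df.index.duplicated().any():
        if duplicate_policy == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dups[:5]}")
        df = df[~df.index.duplicated(keep="first")]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}") from exc
    if df.isna().any().any():
        if missing_policy == "error":
            raise ValueError(f"missing entries in {path} under missing_policy='error'")
        if missing_policy == "drop_gene":
            df = df.dropna(axis=0)
        else:
            df = df.fillna(0.0)
    return ExpressionMatrix.from_frame(df, scale=scale)


def write_expression(x: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    x.to_frame().to_csv(path, sep="\t", float_format=float_format,
                        index_label="gene")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read sample annotations from a TSV with columns sample_id, source,
    class_label (empty allowed); extra columns go into ``extra``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    extra_cols = [c for c in df.columns if c not in ("sample_id", "source", "class_label")]
    out = []
    for _, row in df.iterrows():
        label = row.get("class_label", "") or None
        out.append(SampleAnnotation(
            sample_id=row["sample_id"],
            source=row["source"],
            class_label=label,
            extra={c: row[c] for c in extra_cols},
        ))
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in annotations")
    return out


def write_annotations(annotations: list[SampleAnnotation], path) -> None:
    extra_cols = sorted({k for a in annotations for k in a.extra})
    rows = []
    for a in annotations:
        row = {"sample_id": a.sample_id, "source": a.source,
               "class_label": a.class_label or ""}
        row.update({c: a.extra.get(c, "") for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    coll = GeneSetCollection()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0].strip(), fields[1].strip()
            coll.add(name, fields[2:], desc)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(genes)) + "\n")


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, same order in both."""
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not common:
        raise ValueError("empty gene intersection")
    return a.subset_genes(common), b.subset_genes(common)
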