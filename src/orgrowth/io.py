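"""Readers and writers for the pipeline's tabular and image formats.

Tab-separated UTF-8 with a header row is the canonical dialect; CSV is
accepted on read (the delimiter is sniffed). Gene identifiers are opaque
strings — HGNC symbols are expected but never validated, and no network
access ever happens. Binary masks and stacks travel as single- or
multi-page TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .enrichment import GeneSet, normalize_gene_id
from .errors import ConfigError, SchemaError

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_deg_table",
    "write_deg_table",
    "read_gene_set",
    "write_gene_set",
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "read_mask",
    "read_stack",
    "write_tiff",
    "sha256_of",
]

_DEG_ALIASES = {
    "gene_id": {"gene_id", "gene"},
    "log2fc": {"log2fc", "log2foldchange"},
    "pvalue": {"pvalue", "p_value", "p"},
    "padj": {"padj", "p_adj", "fdr"},
}


def _read_any_sep(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_deg_table(path) -> pd.DataFrame:
    """Read a differential-expression table (TSV/CSV).

    Accepts case-insensitive header aliases (gene/gene_id,
    log2FoldChange/log2fc, ...); returns canonical columns
    (gene_id, log2fc, pvalue, padj). Duplicate gene rows are an error.
    """
    raw = _read_any_sep(path)
    lower = {c.lower(): c for c in raw.columns}
    mapping = {}
    for canon, aliases in _DEG_ALIASES.items():
        found = [lower[a] for a in aliases if a in lower]
        if not found:
            raise SchemaError(
                f"{path}: missing required column {canon!r} "
                f"(accepted aliases: {sorted(aliases)})"
            )
        mapping[found[0]] = canon
    table = raw.rename(columns=mapping)[list(_DEG_ALIASES)]
    dup = table["gene_id"][table["gene_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate gene rows: {sorted(set(dup))[:10]}")
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set: one ID per line, or a two-column TSV whose second
    column holds the IDs. Duplicates are dropped with a warning."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.strip("\r\n").strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise SchemaError(f"{path}: empty gene-set file")
    ids = [ln.split("\t")[1] if "\t" in ln else ln for ln in lines]
    norm = [normalize_gene_id(g) for g in ids]
    if len(set(norm)) < len(norm):
        warnings.warn(f"{path}: {len(norm) - len(set(norm))} duplicate gene ids dropped")
    return GeneSet(name or Path(path).stem, norm)


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.ids)) + "\n", encoding="utf-8")


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression matrix: first column gene IDs, header row
    of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicate gene ids in expression matrix")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    """Generic tabular read (morphometry / section-count / reference CSVs)."""
    return _read_any_sep(path)


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_mask(path, pixel_size=(1.0, 1.0)):
    """Read a single-page binary TIFF mask; returns (bool array, pixel_size)."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise SchemaError(f"{path}: expected a single-plane 2-D mask, got {arr.ndim}-D")
    return arr.astype(bool), tuple(pixel_size)


def read_stack(path, voxel_size=(1.0, 1.0, 1.0)):
    """Read a multi-page binary TIFF stack; returns (bool array, voxel_size)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise SchemaError(f"{path}: expected a 3-D stack, got {arr.ndim}-D")
    return arr.astype(bool), tuple(voxel_size)


def write_tiff(arr, path) -> None:
    tifffile.imwrite(path, np.asarray(arr).astype(np.uint8))


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Run-wide configuration with the pipeline's standing defaults:

    DE significance alpha 0.05 (strict <), 10,000 permutations, top 1000
    most highly expressed genes for identity mapping, S-phase length
    4.5 h.
    """

    seed: int = 0
    paths: dict = field(default_factory=dict)
    alpha: float = 0.05
    n_perm: int = 10000
    top_n_genes: int = 1000
    t_s_hours: float = 4.5
    report_style: str = "full_precision"
    stages: tuple[str, ...] = (
        "simulate",
        "morpho",
        "lmm",
        "cellcycle",
        "enrich",
        "reversal",
        "map_identity",
    )

    def __post_init__(self) -> None:
        if self.report_style not in ("full_precision", "paper_rounded"):
            raise ConfigError(f"unknown report_style {self.report_style!r}")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        self.stages = tuple(self.stages)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)
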