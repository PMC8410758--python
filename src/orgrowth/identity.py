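"""Transcriptome identity mapping against a labeled reference atlas.

A bulk expression profile is assigned to its most similar reference sample
(structure x developmental age) by Pearson correlation computed over the
most highly expressed genes of the query — "most highly expressed" meaning
highest mean across query samples. When inputs are counts, correlations
are computed on the log2(x+1) scale; already-summarized values are
correlated as given.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .enrichment import GeneSet, normalize_gene_id

__all__ = ["top_expressed_genes", "mean_profile", "correlate_profiles"]


def top_expressed_genes(expr: pd.DataFrame, n: int = 1000) -> GeneSet:
    """The n genes with the highest mean expression across samples.

    Ties are broken by gene-id lexicographic order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(expr):
        raise ValueError(f"n={n} exceeds the gene count ({len(expr)})")
    means = expr.mean(axis=1)
    order = (
        pd.DataFrame({"gene_id": expr.index.astype(str), "mean": means.to_numpy()})
        .sort_values(["mean", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    return GeneSet(f"top{n}_expressed", order["gene_id"].head(n))


def mean_profile(expr: pd.DataFrame) -> pd.Series:
    """Mean expression per gene across samples."""
    return expr.mean(axis=1)


def correlate_profiles(
    query: pd.Series,
    atlas: pd.DataFrame,
    genes: GeneSet,
    counts: bool = True,
) -> pd.DataFrame:
    """Pearson r of the query against every atlas profile on a gene subset.

    Returns a frame (profile_label, pearson_r, rank) sorted by descending
    r, ties broken lexicographically by label; profiles with zero variance
    on the intersected genes get undefined r and are ranked last. The
    number of genes actually used is stored in ``result.attrs
    ['n_genes_used']``. Intersection below 90% of the requested set warns;
    below 10 shared genes it is an error.
    """
    qindex = pd.Index([normalize_gene_id(g) for g in query.index])
    aindex = pd.Index([normalize_gene_id(g) for g in atlas.index])
    wanted = pd.Index(sorted(genes.ids))
    shared = wanted.intersection(qindex).intersection(aindex)
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} of {len(wanted)} requested genes shared "
            "between query and atlas (need >= 10)"
        )
    if len(shared) < 0.9 * len(wanted):
        warnings.warn(
            f"only {len(shared)}/{len(wanted)} requested genes found in both "
            "query and atlas"
        )

    q = query.set_axis(qindex).loc[shared].to_numpy(dtype=float)
    a = atlas.set_axis(aindex, axis=0).loc[shared].to_numpy(dtype=float)
    if counts:
        q = np.log2(q + 1.0)
        a = np.log2(a + 1.0)

    qc = q - q.mean()
    qn = float(np.sqrt(np.sum(qc**2)))
    ac = a - a.mean(axis=0, keepdims=True)
    an = np.sqrt(np.sum(ac**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (qc @ ac) / (qn * an)
    bad = (an == 0) | (qn == 0) | ~np.isfinite(r)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} profiles have zero variance on the gene subset; "
            "their correlation is undefined and they are ranked last"
        )
    r = np.clip(r, -1.0, 1.0)
    # snap round-off at the boundary so a self-match reports r = 1.0 exactly
    r = np.where(np.abs(r) > 1.0 - 1e-12, np.sign(r), r)
    r = np.where(bad, np.nan, r)

    out = pd.DataFrame({"profile_label": atlas.columns.astype(str), "pearson_r": r})
    out = out.sort_values(
        ["pearson_r", "profile_label"],
        ascending=[False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_genes_used"] = int(len(shared))
    return out
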