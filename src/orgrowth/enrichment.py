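"""Permutation-null gene-set enrichment and its closed-form oracle.

The framework judges an observed overlap x between a query gene set (for
example, the differentially expressed genes of a contrast) and a target
annotation set against overlaps of equal-size gene lists drawn uniformly
without replacement from a gene universe. The null draws give sample
moments (mu, sigma); significance is summarized as z = (x - mu) / sigma
with a two-sided normal-tail p-value, and an empirical permutation p is
reported alongside. The exact law of the null overlap is hypergeometric,
so :func:`hypergeometric_moments` provides a closed-form cross-check.

Two applications beyond plain set overlap are included: direction-reversal
concordance between a disease and a rescue contrast (evidence of phenotype
rescue), and enrichment among the top-|loading| genes of a principal
component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateNullError, SchemaError

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "normalize_gene_id",
    "significant_genes",
    "overlap_count",
    "permutation_enrichment",
    "hypergeometric_moments",
    "direction_reversal",
    "top_loading_genes",
    "pc_loadings",
    "p_from_z",
]


def normalize_gene_id(gene_id: str) -> str:
    """Case-fold and strip whitespace; no alias resolution is attempted."""
    return str(gene_id).strip().casefold()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers, normalized on construction."""

    name: str
    ids: frozenset

    def __init__(self, name: str, ids) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "ids", frozenset(normalize_gene_id(g) for g in ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene_id: str) -> bool:
        return normalize_gene_id(gene_id) in self.ids


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap against a permutation null.

    ``p_two_sided`` is the normal-tail p from z (primary, per the z-score
    formulation); ``p_empirical`` is ((#{|null - mu| >= |x - mu|}) + 1) /
    (n_perm + 1).
    """

    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    p_two_sided: float
    p_empirical: float
    n_perm: int
    seed: int | None
    universe_size: int
    query_size: int
    target_size: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def p_from_z(z: float) -> float:
    """Two-sided normal-tail p-value, 2 * Phi-bar(|z|)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(table: pd.DataFrame, alpha: float = 0.05, adjust: bool = False,
                      name: str | None = None) -> GeneSet:
    """Genes with padj strictly below ``alpha``.

    ``adjust=True`` computes BH-adjusted p-values from the raw ``pvalue``
    column instead of requiring ``padj``.
    """
    if "gene_id" not in table.columns:
        raise SchemaError("DE table lacks a 'gene_id' column")
    if adjust:
        if "pvalue" not in table.columns:
            raise SchemaError("DE table lacks a 'pvalue' column for BH adjustment")
        padj = bh_adjust(table["pvalue"].to_numpy())
    else:
        if "padj" not in table.columns:
            raise SchemaError("DE table lacks a 'padj' column")
        padj = table["padj"].to_numpy(dtype=float)
    sig = table.loc[padj < alpha, "gene_id"]
    if len(table) == 0:
        warnings.warn("empty DE table: returning an empty gene set")
    return GeneSet(name or f"padj<{alpha}", sig)


def overlap_count(a: GeneSet, b: GeneSet) -> int:
    """Size of the intersection after identifier normalization."""
    return len(a.ids & b.ids)


def hypergeometric_moments(n_query: int, n_target: int, n_universe: int) -> tuple[float, float]:
    """Exact mean and SD of the overlap of a uniform random size-n_query
    subset of the universe with a fixed size-n_target subset."""
    if n_universe < 2:
        raise ValueError("universe must contain at least 2 genes")
    if n_query > n_universe or n_target > n_universe:
        raise ValueError("query/target cannot exceed the universe")
    mu = n_query * n_target / n_universe
    var = (
        mu
        * (1.0 - n_target / n_universe)
        * (n_universe - n_query)
        / (n_universe - 1.0)
    )
    return float(mu), float(math.sqrt(max(var, 0.0)))


def _null_overlaps(rng: np.random.Generator, n_universe: int, n_query: int,
                   target_mask: np.ndarray, n_perm: int) -> np.ndarray:
    out = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        draw = rng.choice(n_universe, size=n_query, replace=False)
        out[i] = int(target_mask[draw].sum())
    return out


def permutation_enrichment(
    query: GeneSet,
    target: GeneSet,
    universe,
    n_perm: int = 10000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Overlap enrichment of ``query`` with ``target`` under equal-size
    random draws from ``universe`` (without replacement).

    ``universe`` may be a GeneSet or any iterable of gene ids and must
    contain both query and target.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    uni = universe.ids if isinstance(universe, GeneSet) else frozenset(
        normalize_gene_id(g) for g in universe
    )
    if not query.ids:
        raise ValueError("query gene set is empty")
    if not target.ids:
        raise ValueError("target gene set is empty")
    if not query.ids <= uni:
        missing = sorted(query.ids - uni)[:5]
        raise ValueError(f"query is not a subset of the universe (e.g. {missing})")
    if not target.ids <= uni:
        missing = sorted(target.ids - uni)[:5]
        raise ValueError(f"target is not a subset of the universe (e.g. {missing})")

    uni_arr = np.array(sorted(uni))
    n_universe = len(uni_arr)
    target_mask = np.isin(uni_arr, np.array(sorted(target.ids)))
    x = overlap_count(query, target)

    rng = np.random.default_rng(seed)
    nulls = _null_overlaps(rng, n_universe, len(query.ids), target_mask, n_perm)
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError(
            "permutation null has zero variance "
            f"(universe={n_universe}, query={len(query.ids)}, target={len(target.ids)}); "
            "z is undefined — is the target (nearly) the whole universe?"
        )
    z = (x - mu) / sd
    p_emp = (int(np.sum(np.abs(nulls - mu) >= abs(x - mu))) + 1) / (n_perm + 1)
    return EnrichmentResult(
        observed_overlap=x,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_two_sided=p_from_z(z),
        p_empirical=float(p_emp),
        n_perm=n_perm,
        seed=seed,
        universe_size=n_universe,
        query_size=len(query.ids),
        target_size=len(target.ids),
    )


def direction_reversal(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    alpha: float = 0.05,
    universe=None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[GeneSet, EnrichmentResult]:
    """Genes significant in both contrasts with opposite effect signs,
    with a permutation test of how many reversals would occur by chance.

    The null draws random sets of size |significant in b| from the
    universe (default: all genes tested in ``deg_a``); each drawn gene that
    is significant in contrast a is counted as a reversal with probability
    1/2 (a fair-coin sign assignment). Genes whose log2fc is exactly zero
    are excluded with a warning.
    """
    for name, t in (("deg_a", deg_a), ("deg_b", deg_b)):
        for col in ("gene_id", "log2fc", "padj"):
            if col not in t.columns:
                raise SchemaError(f"{name} lacks required column {col!r}")

    def _clean(t: pd.DataFrame, name: str) -> pd.DataFrame:
        zero = t["log2fc"] == 0.0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} genes with log2fc == 0 excluded from {name}"
            )
        t = t.loc[~zero].copy()
        t["gene_id"] = t["gene_id"].map(normalize_gene_id)
        return t

    a = _clean(deg_a, "deg_a")
    b = _clean(deg_b, "deg_b")
    sig_a = a.loc[a["padj"] < alpha].set_index("gene_id")["log2fc"]
    sig_b = b.loc[b["padj"] < alpha].set_index("gene_id")["log2fc"]
    shared = sig_a.index.intersection(sig_b.index)
    rev = shared[np.sign(sig_a.loc[shared]).to_numpy() == -np.sign(sig_b.loc[shared]).to_numpy()]
    reversed_set = GeneSet("direction_reversed", rev)

    uni = universe.ids if isinstance(universe, GeneSet) else (
        frozenset(normalize_gene_id(g) for g in universe) if universe is not None
        else frozenset(a["gene_id"])
    )
    uni_arr = np.array(sorted(uni))
    n_universe = len(uni_arr)
    siga_mask = np.isin(uni_arr, np.array(sorted(frozenset(sig_a.index))))
    k = len(frozenset(sig_b.index))
    if k == 0 or k > n_universe:
        raise ValueError("no significant genes in deg_b, or universe too small")

    rng = np.random.default_rng(seed)
    hits = _null_overlaps(rng, n_universe, k, siga_mask, n_perm)
    nulls = rng.binomial(hits, 0.5)
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError("direction-reversal null has zero variance")
    x = len(reversed_set)
    z = (x - mu) / sd
    p_emp = (int(np.sum(np.abs(nulls - mu) >= abs(x - mu))) + 1) / (n_perm + 1)
    result = EnrichmentResult(
        observed_overlap=x,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_two_sided=p_from_z(z),
        p_empirical=float(p_emp),
        n_perm=n_perm,
        seed=seed,
        universe_size=n_universe,
        query_size=k,
        target_size=int(siga_mask.sum()),
    )
    return reversed_set, result


def top_loading_genes(loadings: pd.Series, k: int, name: str | None = None) -> GeneSet:
    """The k genes with the largest absolute loading on one component.

    Ties are broken by gene-id lexicographic order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(loadings):
        raise ValueError(f"k={k} exceeds the number of genes ({len(loadings)})")
    order = (
        pd.DataFrame({"gene_id": loadings.index.astype(str), "absw": loadings.abs().to_numpy()})
        .sort_values(["absw", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    return GeneSet(name or f"top{k}_loadings", order["gene_id"].head(k))


def pc_loadings(expr: pd.DataFrame, n_components: int = 2, counts: bool = True):
    """Per-gene principal-component loadings of a genes x samples matrix.

    Counts are log2(x+1)-transformed; genes are centered across samples.
    Returns (loadings frame genes x PC1..PCk, explained variance ratios).
    """
    x = expr.to_numpy(dtype=float)
    if counts:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    # samples as observations: SVD of samples x genes
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    n_components = min(n_components, len(s))
    evr = (s**2) / float(np.sum(s**2)) if np.sum(s**2) > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(vt[:n_components].T, index=expr.index, columns=cols)
    return loadings, evr[:n_components]
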