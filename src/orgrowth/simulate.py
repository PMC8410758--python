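"""Synthetic data generators for the organoid-overgrowth analysis pipeline.

Every generator is deterministic under a fixed seed and emits the plain
containers (pandas frames, numpy arrays) the downstream modules consume.
Defaults mirror the design of the study being emulated: three iPSC lines per
genotype with 6-7 organoids per line measured over weeks in culture, three
histology sections per organoid for BrdU/Ki67 counts, and bulk RNA-seq-scale
negative-binomial count matrices with a planted differentially-expressed
(DE) gene set, a planted disease-annotation set overlapping it by a known
count, and a rescue condition that reverses a chosen fraction of DE effect
signs. Organoid growth is modeled on the log scale so line and residual
effects are multiplicative, matching fold-change reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .enrichment import GeneSet
from .errors import ConfigError

GENOTYPES = ("control", "case")

__all__ = [
    "MorphoSimConfig",
    "ExprSimConfig",
    "ExpressionSim",
    "gen_morphometry",
    "gen_image_pair",
    "gen_brdu_ki67",
    "gen_expression",
    "gen_atlas",
]


@dataclass(frozen=True)
class MorphoSimConfig:
    """Design of a simulated organoid growth experiment.

    Areas are mm^2, volumes mm^3, weeks are timepoints in culture. The
    genotype effect is scaled linearly in time so that case organoids reach
    ``genotype_fold`` times the control area at the final week and show no
    difference at the first week. ``line_sd`` and ``residual_sd`` are
    log-scale standard deviations (line random intercept; per-measurement
    noise). ``growth_rate`` is the log-area increase per week shared by all
    organoids.
    """

    n_lines_per_genotype: int = 3
    n_organoids_per_line: int = 7
    weeks: tuple[float, ...] = (4.0, 9.0, 13.0)
    baseline_area: float = 1.0
    genotype_fold: float = 1.5
    line_sd: float = 0.10
    residual_sd: float = 0.15
    growth_rate: float = 0.12
    volume_slope: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines_per_genotype <= 0 or self.n_organoids_per_line <= 0:
            raise ConfigError("counts must be positive")
        if self.genotype_fold <= 0:
            raise ConfigError("genotype_fold must be > 0")
        if self.line_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.baseline_area <= 0:
            raise ConfigError("baseline_area must be > 0")
        weeks = tuple(float(w) for w in self.weeks)
        if len(weeks) == 0 or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigError("weeks must be non-empty and strictly increasing")
        object.__setattr__(self, "weeks", weeks)


def gen_morphometry(cfg: MorphoSimConfig) -> pd.DataFrame:
    """Simulate per-organoid areas and volumes over time.

    Returns a frame with one row per organoid per week and columns
    ``line_id, genotype, organoid_id, week, area_mm2, volume_mm3``.
    log(area) = log(baseline) + growth_rate * (week - first week)
    + genotype effect ramping to log(genotype_fold) at the final week
    + line intercept + residual noise; volume = volume_slope * area with
    multiplicative log-normal noise of the same residual SD.
    """
    rng = np.random.default_rng(cfg.seed)
    weeks = np.asarray(cfg.weeks, dtype=float)
    w0, w1 = weeks[0], weeks[-1]
    span = (w1 - w0) if w1 > w0 else 1.0
    log_fold = math.log(cfg.genotype_fold)

    rows = []
    for genotype, prefix in zip(GENOTYPES, ("C", "P")):
        for li in range(cfg.n_lines_per_genotype):
            line_id = f"{prefix}{li + 1}"
            b_line = rng.normal(0.0, cfg.line_sd) if cfg.line_sd > 0 else 0.0
            for oi in range(cfg.n_organoids_per_line):
                organoid_id = f"{line_id}_o{oi + 1}"
                for w in weeks:
                    ramp = (w - w0) / span
                    eff = log_fold * ramp if genotype == "case" else 0.0
                    eps = rng.normal(0.0, cfg.residual_sd) if cfg.residual_sd > 0 else 0.0
                    area = math.exp(
                        math.log(cfg.baseline_area)
                        + cfg.growth_rate * (w - w0)
                        + eff
                        + b_line
                        + eps
                    )
                    veps = rng.normal(0.0, cfg.residual_sd) if cfg.residual_sd > 0 else 0.0
                    volume = cfg.volume_slope * area * math.exp(veps)
                    rows.append((line_id, genotype, organoid_id, w, area, volume))
    return pd.DataFrame(
        rows,
        columns=["line_id", "genotype", "organoid_id", "week", "area_mm2", "volume_mm3"],
    )


def gen_image_pair(
    radius_voxels: float,
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    jitter: float = 0.0,
    shape: tuple[int, int, int] | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Binary ellipsoid-like 3D stack plus its exact voxel-count volume.

    ``anisotropy`` scales the (z, y, x) semi-axes of the ellipsoid relative
    to ``radius_voxels``; ``jitter`` flips each boundary-shell voxel with the
    given probability to roughen the surface. The returned volume is the
    foreground voxel count of the *returned* stack times the voxel volume,
    so it remains exact under jitter.
    """
    if radius_voxels < 2:
        raise ConfigError("radius_voxels must be >= 2")
    if not 0.0 <= jitter <= 1.0:
        raise ConfigError("jitter must be in [0, 1]")
    semi = radius_voxels * np.asarray(anisotropy, dtype=float)
    if np.any(semi <= 0):
        raise ConfigError("anisotropy must be positive")
    vsize = np.asarray(voxel_size, dtype=float)
    if np.any(vsize <= 0):
        raise ConfigError("voxel_size must be positive")
    if shape is None:
        shape = tuple(int(math.ceil(2 * s)) + 5 for s in semi)
    shape = tuple(int(s) for s in shape)
    if any(2 * s + 1 > d for s, d in zip(semi, shape)):
        raise ConfigError(f"radius {semi} exceeds stack bounds {shape}")

    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.indices(shape, dtype=float)
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    stack = d2 <= 1.0
    if jitter > 0:
        rng = np.random.default_rng(seed)
        shell = ndimage.binary_dilation(stack) ^ ndimage.binary_erosion(stack)
        flip = shell & (rng.random(shape) < jitter)
        stack = stack ^ flip
    true_volume = float(stack.sum()) * float(np.prod(vsize))
    return stack, true_volume


def gen_brdu_ki67(
    n_lines: int = 3,
    n_orgs: int = 3,
    n_sections: int = 3,
    n_ki67_per_section: int = 200,
    labeling_index: float | dict[str, float] = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-section BrdU/Ki67 counts with a planted labeling index.

    ``labeling_index`` is the true BrdU+Ki67+ / Ki67+ fraction, either a
    scalar (both genotypes) or a mapping genotype -> fraction. Defaults
    correspond to cell-cycle lengths of ~83 h (control) and ~54 h (case)
    for a 4.5 h S-phase. Each section draws its Ki67+ count from a Poisson
    around ``n_ki67_per_section`` and its double-positive count from
    Binomial(n_ki67, labeling_index); PAX6+ and total-nuclei columns are
    included so marker fractions can be computed downstream.
    """
    if labeling_index is None:
        labeling_index = {"control": 4.5 / 83.0, "case": 4.5 / 54.0}
    if not isinstance(labeling_index, dict):
        labeling_index = {g: float(labeling_index) for g in GENOTYPES}
    for g, li in labeling_index.items():
        if not 0.0 < li <= 1.0:
            raise ConfigError(f"labeling index for {g!r} must be in (0, 1], got {li}")
    if min(n_lines, n_orgs, n_sections, n_ki67_per_section) <= 0:
        raise ConfigError("counts must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for genotype, prefix in zip(GENOTYPES, ("C", "P")):
        li_true = labeling_index.get(genotype)
        if li_true is None:
            continue
        for l in range(n_lines):
            line_id = f"{prefix}{l + 1}"
            for o in range(n_orgs):
                organoid_id = f"{line_id}_o{o + 1}"
                for s in range(n_sections):
                    n_ki67 = int(rng.poisson(n_ki67_per_section))
                    n_ki67 = max(n_ki67, 1)
                    n_double = int(rng.binomial(n_ki67, li_true))
                    n_nuclei = n_ki67 + int(rng.poisson(2.0 * n_ki67))
                    # BrdU+ cells outside the Ki67+ pool (exited the cycle
                    # during the pulse) are a small extra fraction.
                    n_brdu = n_double + int(rng.binomial(n_nuclei - n_ki67, 0.02))
                    n_pax6 = int(rng.binomial(n_nuclei, 0.45))
                    rows.append(
                        (line_id, genotype, organoid_id, s, n_brdu, n_ki67, n_double, n_pax6, n_nuclei)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "line_id",
            "genotype",
            "organoid_id",
            "section_idx",
            "n_brdu",
            "n_ki67",
            "n_double",
            "n_pax6",
            "n_nuclei",
        ],
    )


@dataclass(frozen=True)
class ExprSimConfig:
    """Design of a simulated bulk RNA-seq experiment with three groups.

    Gene baseline means are log-normal (natural-log mean/SD
    ``nb_mean_log_mean`` / ``nb_mean_log_sd``); counts are negative binomial
    with dispersion ``nb_dispersion`` (var = mu + disp * mu^2). ``n_de``
    genes receive a log2 fold-change in the patient group; the rescue group
    returns to the control level for a ``rescue_reversal_fraction`` subset
    (so their rescue-vs-patient sign is opposite the patient-vs-control
    sign) and stays at the patient level otherwise. A disease-annotation
    set of ``n_disease_set`` genes overlaps the DE set by exactly
    ``planted_overlap``. A batch shift of SD ``batch_shift_sd`` (natural
    log) is applied to a random ``batch_gene_fraction`` of genes, disjoint
    from the DE set, in the rescue-batch samples.
    """

    n_genes: int = 20000
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("control", "patient", "rescue")
    nb_mean_log_mean: float = 4.0
    nb_mean_log_sd: float = 1.5
    nb_dispersion: float = 0.05
    n_de: int = 339
    de_log2fc_sd: float = 1.0
    n_disease_set: int = 980
    planted_overlap: int = 19
    rescue_reversal_fraction: float = 0.2
    batch_gene_fraction: float = 0.05
    batch_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("counts must be positive")
        if self.n_de < 0 or self.n_disease_set < 0:
            raise ConfigError("set sizes must be >= 0")
        if self.planted_overlap > min(self.n_de, self.n_disease_set):
            raise ConfigError(
                "planted_overlap exceeds min(n_de, n_disease_set): "
                f"{self.planted_overlap} > min({self.n_de}, {self.n_disease_set})"
            )
        if self.n_de + (self.n_disease_set - self.planted_overlap) > self.n_genes:
            raise ConfigError("DE and disease sets do not fit in the gene universe")
        if not 0.0 <= self.rescue_reversal_fraction <= 1.0:
            raise ConfigError("rescue_reversal_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")


@dataclass
class ExpressionSim:
    """Bundle returned by :func:`gen_expression`.

    ``counts`` is genes x samples; ``truth`` holds the planted per-gene
    effects; ``deg_patient`` / ``deg_rescue`` are DE-table-shaped frames
    (gene_id, log2fc, pvalue, padj) for the patient-vs-control and
    rescue-vs-patient contrasts, emulating upstream DE caller output;
    ``sample_info`` maps samples to group and batch.
    """

    counts: pd.DataFrame
    truth: pd.DataFrame
    disease_set: GeneSet
    batch_genes: GeneSet
    deg_patient: pd.DataFrame
    deg_rescue: pd.DataFrame
    sample_info: pd.DataFrame


def gen_expression(cfg: ExprSimConfig) -> ExpressionSim:
    """Simulate NB counts with planted DE, disease-set overlap and rescue."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    base_log_mean = rng.normal(cfg.nb_mean_log_mean, cfg.nb_mean_log_sd, size=n)

    perm = rng.permutation(n)
    de_idx = perm[: cfg.n_de]
    non_de = perm[cfg.n_de :]

    # planted patient-vs-control log2 fold-changes, bounded away from zero
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de)
    l2fc = signs * (0.25 + np.abs(rng.normal(0.0, cfg.de_log2fc_sd, size=cfg.n_de)))
    reversed_flags = rng.random(cfg.n_de) < cfg.rescue_reversal_fraction

    # disease-annotation set: exact overlap with the DE set by construction
    overlap_genes = rng.choice(de_idx, size=cfg.planted_overlap, replace=False) if cfg.planted_overlap else np.array([], dtype=int)
    rest = rng.choice(non_de, size=cfg.n_disease_set - cfg.planted_overlap, replace=False)
    disease_idx = np.concatenate([overlap_genes, rest]).astype(int)

    # batch genes: disjoint from the DE set
    n_batch = int(round(cfg.batch_gene_fraction * n))
    n_batch = min(n_batch, len(non_de))
    batch_idx = rng.choice(non_de, size=n_batch, replace=False).astype(int)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=n_batch)

    samples, group_of, batch_of = [], [], []
    for g in cfg.groups:
        for i in range(cfg.n_samples_per_group):
            samples.append(f"{g}_{i + 1}")
            group_of.append(g)
            batch_of.append("B2" if g == "rescue" else "B1")

    log_mu = np.tile(base_log_mean[:, None], (1, len(samples)))
    ln2 = math.log(2.0)
    for j, g in enumerate(group_of):
        if g == "patient":
            log_mu[de_idx, j] += l2fc * ln2
        elif g == "rescue":
            # reversed genes return to the control level; others keep the
            # patient-level shift
            log_mu[de_idx, j] += np.where(reversed_flags, 0.0, l2fc) * ln2
        if batch_of[j] == "B2":
            log_mu[batch_idx, j] += batch_shift
    mu = np.exp(log_mu)

    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc_patient": 0.0,
            "log2fc_rescue": 0.0,
            "is_de": False,
            "is_reversed": False,
        }
    ).set_index("gene_id")
    truth.iloc[de_idx, truth.columns.get_loc("log2fc_patient")] = l2fc
    truth.iloc[de_idx, truth.columns.get_loc("is_de")] = True
    rescue_l2fc = np.where(reversed_flags, -l2fc, 0.0)
    truth.iloc[de_idx, truth.columns.get_loc("log2fc_rescue")] = rescue_l2fc
    truth.iloc[de_idx, truth.columns.get_loc("is_reversed")] = reversed_flags
    truth = truth.reset_index()

    deg_patient = _deg_table(rng, genes, de_idx, l2fc)
    rev_idx = de_idx[reversed_flags]
    deg_rescue = _deg_table(rng, genes, rev_idx, -l2fc[reversed_flags])

    sample_info = pd.DataFrame({"sample_id": samples, "group": group_of, "batch": batch_of})
    return ExpressionSim(
        counts=counts_df,
        truth=truth,
        disease_set=GeneSet("disease_set", genes[disease_idx]),
        batch_genes=GeneSet("batch_genes", genes[batch_idx]),
        deg_patient=deg_patient,
        deg_rescue=deg_rescue,
        sample_info=sample_info,
    )


def _deg_table(rng: np.random.Generator, genes: np.ndarray, sig_idx: np.ndarray, sig_l2fc: np.ndarray) -> pd.DataFrame:
    """DE-table-shaped frame whose significant rows are exactly ``sig_idx``.

    Emulates the output of an upstream DE caller: planted genes get small
    p-values (padj < 0.05), all other genes get null p-values and a small
    non-zero log2fc.
    """
    n = len(genes)
    l2fc = rng.normal(0.0, 0.05, size=n)
    # avoid exact zeros so effect signs are always defined
    l2fc = np.where(l2fc == 0.0, 1e-6, l2fc)
    pvalue = rng.uniform(0.05, 1.0, size=n)
    padj = np.minimum(1.0, pvalue + rng.uniform(0.1, 0.5, size=n))
    l2fc[sig_idx] = sig_l2fc
    pvalue[sig_idx] = 10 ** rng.uniform(-12, -4, size=len(sig_idx))
    padj[sig_idx] = 10 ** rng.uniform(-8, math.log10(0.04), size=len(sig_idx))
    return pd.DataFrame({"gene_id": genes, "log2fc": l2fc, "pvalue": pvalue, "padj": padj})


_STRUCTURES = ("DFC", "OFC", "V1C", "HIP", "AMY", "STR", "MGE", "CBC")
_AGES = ("8pcw", "9pcw", "12pcw", "16pcw", "21pcw")


def gen_atlas(
    n_structures: int = 8,
    n_ages: int = 5,
    n_genes: int = 500,
    target_label: str = "DFC|9pcw",
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled reference profiles plus a query built from one of them.

    Returns ``(atlas, query)`` where atlas is genes x "structure|age"
    labels of positive expression values and query equals the target
    profile perturbed by multiplicative log-normal noise of SD
    ``noise_sd`` — so with small noise the target ranks first by Pearson r.
    """
    if n_structures > len(_STRUCTURES) or n_ages > len(_AGES):
        raise ConfigError(
            f"at most {len(_STRUCTURES)} structures and {len(_AGES)} ages available"
        )
    labels = [f"{s}|{a}" for s in _STRUCTURES[:n_structures] for a in _AGES[:n_ages]]
    if target_label not in labels:
        raise ConfigError(f"target_label {target_label!r} not among generated labels")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    values = np.exp(rng.normal(3.0, 1.5, size=(n_genes, len(labels))))
    atlas = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=labels)
    noise = np.exp(rng.normal(0.0, noise_sd, size=n_genes)) if noise_sd > 0 else 1.0
    query = atlas[target_label] * noise
    query.name = "query"
    return atlas, query
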