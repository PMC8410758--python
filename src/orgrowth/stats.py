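"""Inferential machinery: random-intercept mixed model with likelihood-ratio
tests, t-tests, distribution tails, reference z-scores, and ordinal scores.

The mixed model is a Gaussian random-intercept model

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_line^2),
                                      e_ij ~ N(0, sigma_resid^2)

with genotype as the fixed effect of interest and cell line as the grouping
factor. Estimation is full maximum likelihood (not REML) because the
likelihood-ratio tests compare models that differ in their fixed effects,
and REML log-likelihoods are not comparable across fixed-effect
structures. The likelihood is profiled over the variance ratio
lambda = sigma_line^2 / sigma_resid^2: for each candidate lambda the fixed
effects are the generalized-least-squares solution and sigma_resid^2 has a
closed form, leaving a deterministic one-dimensional search (log-spaced
grid refined by golden section, boundary lambda = 0 permitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "LMMFit",
    "LRTResult",
    "TTestResult",
    "SubjectZ",
    "fit_random_intercept",
    "fit_lmm",
    "lrt_genotype",
    "chi2_upper_tail",
    "t_two_sided_p",
    "welch_t",
    "one_sample_t",
    "subject_z",
    "subject_z_from_table",
    "combined_weighted_z",
    "median_score",
]

# response name -> (source column, transform)
RESPONSES = {
    "log_area": ("area_mm2", np.log),
    "log_volume": ("volume_mm3", np.log),
    "log_total_cells": ("total_cells", np.log),
    "labeling_index": ("labeling_index", None),
}


@dataclass(frozen=True)
class LMMFit:
    """Maximum-likelihood fit of the random-intercept model."""

    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma_line: float
    sigma_resid: float
    loglik: float
    n_obs: int
    n_groups: int

    @property
    def genotype_effect(self) -> float:
        """Fixed-effect coefficient of the non-reference genotype."""
        for name, b in zip(self.beta_names, self.beta):
            if name.startswith("genotype"):
                return float(b)
        raise AttributeError("model was fitted without a genotype effect")


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float


_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-6, 3, 60)])


def _profile_stats(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the profiled likelihood."""
    order = np.argsort(groups, kind="mergesort")
    y = y[order]
    x = x[order]
    g = groups[order]
    _, idx, n_g = np.unique(g, return_index=True, return_counts=True)
    bounds = np.append(idx, len(g))
    sx = np.add.reduceat(x, bounds[:-1], axis=0)  # per-group column sums
    sy = np.add.reduceat(y, bounds[:-1])
    return {
        "xtx": x.T @ x,
        "xty": x.T @ y,
        "yty": float(y @ y),
        "sx": sx,
        "sy": sy,
        "n_g": n_g.astype(float),
        "n": len(y),
    }


def _profile_loglik(lam: float, st: dict):
    """Profiled log-likelihood at variance ratio lam, plus beta, sigma^2."""
    n_g = st["n_g"]
    c = lam / (1.0 + lam * n_g)  # shrinkage weight per group
    xtvx = st["xtx"] - (st["sx"].T * c) @ st["sx"]
    xtvy = st["xty"] - st["sx"].T @ (c * st["sy"])
    ytvy = st["yty"] - float(np.sum(c * st["sy"] ** 2))
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design matrix in mixed-model fit") from exc
    rss = ytvy - float(beta @ xtvy)
    # relative floor keeps the likelihood finite (and LRTs exactly zero)
    # when the response is fitted perfectly, e.g. constant data
    rss = max(rss, 1e-12 * (1.0 + st["yty"]))
    n = st["n"]
    sigma2 = rss / n
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0) - 0.5 * float(
        np.sum(np.log1p(lam * n_g))
    )
    return ll, beta, sigma2


def fit_random_intercept(y, x, groups, beta_names: tuple[str, ...] | None = None) -> LMMFit:
    """ML fit of y = X beta + b_group + e via profile likelihood.

    ``x`` must include an intercept column if one is wanted. The search
    over lambda = sigma_line^2 / sigma_resid^2 is a fixed log grid
    (1e-6..1e3, 60 points, plus the lambda = 0 boundary) refined by
    golden-section to 1e-10 relative tolerance — fully deterministic.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    groups = np.asarray(groups)
    st = _profile_stats(y, x, groups)

    lls = np.array([_profile_loglik(l, st)[0] for l in _LAMBDA_GRID])
    best = int(np.argmax(lls))
    lam_best = _LAMBDA_GRID[best]
    if best > 0:
        lo = max(_LAMBDA_GRID[max(best - 1, 0)], 1e-12)
        hi = _LAMBDA_GRID[min(best + 1, len(_LAMBDA_GRID) - 1)]
        neg = lambda t: -_profile_loglik(math.exp(t), st)[0]
        try:
            t_ref = optimize.golden(
                neg, brack=(math.log(lo), math.log(lam_best), math.log(hi)), tol=1e-10
            )
        except ValueError:
            t_ref = optimize.minimize_scalar(
                neg, bounds=(math.log(lo), math.log(hi)), method="bounded",
                options={"xatol": 1e-10},
            ).x
        lam_ref = math.exp(float(t_ref))
        if _profile_loglik(lam_ref, st)[0] > lls[best]:
            lam_best = lam_ref
    ll, beta, sigma2 = _profile_loglik(lam_best, st)
    if beta_names is None:
        beta_names = tuple(f"b{i}" for i in range(x.shape[1]))
    return LMMFit(
        beta=beta,
        beta_names=tuple(beta_names),
        sigma_line=math.sqrt(lam_best * sigma2),
        sigma_resid=math.sqrt(sigma2),
        loglik=float(ll),
        n_obs=st["n"],
        n_groups=len(st["n_g"]),
    )


def _design(records: pd.DataFrame, include_genotype: bool):
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    if include_genotype:
        levels = sorted(records["genotype"].unique())
        if len(levels) < 2:
            raise ValueError(
                "genotype effect requested but only one genotype level present"
            )
        if len(levels) > 2:
            raise ValueError("expected exactly 2 genotype levels, got " + str(levels))
        ref = "control" if "control" in levels else levels[0]
        other = [l for l in levels if l != ref][0]
        cols.append((records["genotype"] == other).to_numpy(dtype=float))
        names.append(f"genotype[{other}]")
    return np.column_stack(cols), tuple(names)


def _response_vector(records: pd.DataFrame, response: str) -> np.ndarray:
    if response in RESPONSES:
        col, transform = RESPONSES[response]
    else:
        col, transform = response, None
    if col not in records.columns:
        raise ValueError(f"records lack column {col!r} for response {response!r}")
    v = records[col].to_numpy(dtype=float)
    return transform(v) if transform is not None else v


def fit_lmm(
    records: pd.DataFrame,
    response: str = "log_area",
    include_genotype: bool = True,
    group: str = "line_id",
) -> LMMFit:
    """Fit the random-intercept model to one week of organoid records.

    ``response`` is one of log_area, log_volume, log_total_cells,
    labeling_index, or any raw column name. Genotype is coded as an
    indicator of the non-control level.
    """
    y = _response_vector(records, response)
    x, names = _design(records, include_genotype)
    return fit_random_intercept(y, x, records[group].to_numpy(), beta_names=names)


def lrt_genotype(records: pd.DataFrame, response: str = "log_area", group: str = "line_id") -> LRTResult:
    """Likelihood-ratio test of the genotype fixed effect (df = 1).

    chi2 = 2 (loglik_full - loglik_null) against a chi-square(1) tail;
    small negative chi2 from optimizer round-off is clamped to zero.
    """
    full = fit_lmm(records, response, include_genotype=True, group=group)
    null = fit_lmm(records, response, include_genotype=False, group=group)
    chi2 = 2.0 * (full.loglik - null.loglik)
    if chi2 < -1e-8:
        raise RuntimeError(f"negative LRT statistic ({chi2:.3g}): optimizer failure")
    chi2 = max(chi2, 0.0)
    return LRTResult(chi2=chi2, df=1, p_value=chi2_upper_tail(chi2, 1))


def chi2_upper_tail(stat: float, df: float) -> float:
    """Chi-square survival function."""
    if stat < 0 or df <= 0:
        raise ValueError("stat must be >= 0 and df > 0")
    return float(sps.chi2.sf(stat, df))


def t_two_sided_p(t_stat: float, df: float) -> float:
    """Two-sided Student-t tail probability."""
    if df <= 0:
        raise ValueError("df must be > 0")
    return float(2.0 * sps.t.sf(abs(t_stat), df))


def welch_t(a, b) -> TTestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t_stat=0.0, df=float(len(a) + len(b) - 2), p_value=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return TTestResult(t_stat=float(t), df=float(df), p_value=t_two_sided_p(t, df))


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of the mean against mu0, two-sided."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 observations")
    if v.var(ddof=1) == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, mu0)
    return TTestResult(t_stat=float(res.statistic), df=float(len(v) - 1), p_value=float(res.pvalue))


@dataclass(frozen=True)
class SubjectZ:
    """A subject's measurement standardized against a reference norm."""

    subject_id: str
    raw_value: float
    ref_mean: float
    ref_sd: float
    z: float


def subject_z(value: float, ref_mean: float, ref_sd: float, subject_id: str = "") -> SubjectZ:
    """z = (value - reference mean) / reference SD."""
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return SubjectZ(
        subject_id=subject_id,
        raw_value=float(value),
        ref_mean=float(ref_mean),
        ref_sd=float(ref_sd),
        z=(float(value) - float(ref_mean)) / float(ref_sd),
    )


def subject_z_from_table(
    value: float,
    sex: str,
    age_months: float,
    reference: pd.DataFrame,
    subject_id: str = "",
) -> SubjectZ:
    """Standardize against a reference-norm table with columns
    (sex, age_months, mean, sd); errors name a missing stratum."""
    for col in ("sex", "age_months", "mean", "sd"):
        if col not in reference.columns:
            raise ValueError(f"reference table lacks column {col!r}")
    row = reference.loc[
        (reference["sex"] == sex) & (reference["age_months"] == age_months)
    ]
    if len(row) == 0:
        raise KeyError(f"no reference row for stratum sex={sex!r}, age_months={age_months}")
    r = row.iloc[0]
    return subject_z(value, float(r["mean"]), float(r["sd"]), subject_id=subject_id)


def combined_weighted_z(z_values, weights=None) -> tuple[float, float]:
    """Stouffer's weighted combination: sum(w z) / sqrt(sum(w^2)).

    Returns (combined z, two-sided normal p).
    """
    z = np.asarray(z_values, dtype=float)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(z):
        raise ValueError("weights and z-values length mismatch")
    if np.any(w < 0) or np.all(w == 0):
        raise ValueError("weights must be >= 0 and not all zero")
    zc = float(np.sum(w * z) / math.sqrt(float(np.sum(w**2))))
    return zc, float(2.0 * sps.norm.sf(abs(zc)))


def median_score(scores) -> int:
    """Middle order statistic of exactly three blinded ordinal scores."""
    s = list(scores)
    if len(s) != 3:
        raise ValueError(f"expected exactly 3 scores, got {len(s)}")
    return int(sorted(s)[1])
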