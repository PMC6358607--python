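"""Post hoc quadratic response-surface analysis of the evaluation library.

After a campaign, all tested formulations (excluding the random initial
generation) are pooled and the log response is modeled as

    Y = K + G_p + sum_j b_j x_j + sum_{i<j} b_ij x_i x_j + sum_j b_jj x_j^2 + eps

with x the coded doses in [-1, 1] and G_p fixed-effect generation-block
contrasts (generation 2 as reference).  Left-censored responses (below the
count-sensitivity threshold) are imputed from a censored-normal maximum
likelihood fit.  Coefficient p-values are Benjamini-Hochberg FDR-adjusted
over the family of main, square and crossproduct terms, and reported as
logworth = -log10(FDR p) for volcano-style screening.

The natural log is used throughout; the base only rescales coefficients
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .engine import EvaluationLibrary
from .space import FactorSpace, coded_dose

__all__ = [
    "impute_censored",
    "build_design",
    "fit_quadratic",
    "fdr_adjust",
    "volcano_table",
    "RegressionResult",
]


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Left-censored imputation


def impute_censored(log_responses, censor_flags, threshold: float,
                    rng: np.random.Generator | None = None,
                    deterministic: bool = False) -> np.ndarray:
    """Complete left-censored log responses.

    A normal distribution is fitted by maximum likelihood to the observed
    log responses, treating censored points as left-censored at
    log(threshold); each censored value is then replaced by a draw from the
    fitted normal truncated above at log(threshold) (or by the truncated
    conditional mean when ``deterministic``).
    """
    y = np.asarray(log_responses, dtype=float).copy()
    flags = np.asarray(censor_flags, dtype=bool)
    if y.shape != flags.shape:
        raise ValueError("log_responses and censor_flags must align")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_cens = int(flags.sum())
    if n_cens == 0:
        return y
    n_obs = int((~flags).sum())
    if n_obs == 0:
        raise AnalysisError("all responses censored; nothing to fit")
    if n_obs < 10:
        raise AnalysisError("need at least 10 uncensored values to fit")

    L = np.log(threshold)
    obs = y[~flags]

    def nll(params):
        mu, log_sd = params
        sd = np.exp(log_sd)
        ll = stats.norm.logpdf(obs, mu, sd).sum()
        ll += n_cens * stats.norm.logcdf(L, mu, sd)
        return -ll

    res = optimize.minimize(nll, x0=[obs.mean(), np.log(obs.std(ddof=1) + 1e-9)],
                            method="Nelder-Mead")
    mu, sd = res.x[0], float(np.exp(res.x[1]))
    a = (L - mu) / sd
    trunc = stats.truncnorm(-np.inf, a, loc=mu, scale=sd)
    if deterministic:
        y[flags] = trunc.mean()
    else:
        rng = rng or np.random.default_rng(0)
        y[flags] = trunc.ppf(rng.uniform(size=n_cens))
    return y


# ---------------------------------------------------------------------------
# Design construction


def build_design(library: EvaluationLibrary, space: FactorSpace,
                 rng: np.random.Generator | None = None,
                 deterministic_imputation: bool = False) -> pd.DataFrame:
    """Replicate-level model matrix from an evaluation library.

    Rows are (formulation, replicate) pairs with generation >= 2 (the
    random initial population is excluded); columns are coded doses, their
    squares and pairwise products, plus generation-block indicators with
    generation 2 as reference.  The response column ``log_y`` holds
    natural-log counts after censored imputation.
    """
    names = [f.name for f in space.factors]
    rows = []
    for levels, entry in library.items():
        x = coded_dose(space, levels)
        for v, g, c in zip(entry.values, entry.generations, entry.censored):
            if g < 2:
                continue
            rows.append((levels, x, g, v, c))
    if not rows:
        raise AnalysisError("library has no responses beyond generation 1")
    gens = sorted({g for _, _, g, _, _ in rows})
    if len(gens) < 1:
        raise AnalysisError("need at least one post-initial generation")

    data: dict[str, list] = {}
    D = space.D
    X = np.array([x for _, x, _, _, _ in rows])
    for j, n in enumerate(names):
        data[n] = X[:, j]
    for j, n in enumerate(names):
        data[f"{n}^2"] = X[:, j] ** 2
    for i in range(D):
        for j in range(i + 1, D):
            data[f"{names[i]}:{names[j]}"] = X[:, i] * X[:, j]
    ref = gens[0]
    for g in gens:
        if g == ref:
            continue
        data[f"gen[{g}]"] = np.array([1.0 if gg == g else 0.0
                                      for _, _, gg, _, _ in rows])
    df = pd.DataFrame(data)
    df.insert(0, "generation", [g for _, _, g, _, _ in rows])
    df.insert(0, "formulation", ["-".join(map(str, lv)) for lv, _, _, _, _ in rows])

    vals = np.array([v for _, _, _, v, _ in rows], dtype=float)
    flags = np.array([c for _, _, _, _, c in rows], dtype=bool)
    if np.any(vals <= 0):
        raise AnalysisError("nonpositive responses cannot be log-transformed")
    log_y = np.log(vals)
    if flags.any():
        threshold = float(vals[flags].min())
        log_y = impute_censored(log_y, flags, threshold, rng=rng,
                                deterministic=deterministic_imputation)
    df["censored"] = flags
    df["log_y"] = log_y
    return df


# ---------------------------------------------------------------------------
# Model fit


@dataclass
class RegressionResult:
    table: pd.DataFrame            # term, estimate, se, p_raw, p_fdr, logworth, significant
    dropped_terms: list[str]       # aliased/collinear terms pruned before fitting
    n_obs: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def _model_columns(df: pd.DataFrame) -> list[str]:
    skip = {"formulation", "generation", "censored", "log_y"}
    return [c for c in df.columns if c not in skip]


def fit_quadratic(design: pd.DataFrame, fdr_alpha: float = 0.05) -> RegressionResult:
    """Ordinary least squares on the full quadratic term set.

    Collinear columns are pruned by QR rank analysis and reported in
    ``dropped_terms`` rather than silently absorbed.  Two-sided t-test
    p-values per coefficient; FDR adjustment over the family of main,
    square and crossproduct terms (block contrasts and the intercept are
    excluded from the family and carry NaN adjusted values).
    """
    cols = _model_columns(design)
    X = design[cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design)), X])
    names = ["intercept"] + cols

    # prune aliased columns via pivoted QR
    q, r, piv = _pivoted_qr(X)
    tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in range(len(names)) if i not in keep]
    if "intercept" in dropped:
        raise AnalysisError("design degenerate: intercept aliased")
    Xk = X[:, keep]
    kept_names = [names[i] for i in keep]
    if Xk.shape[0] <= Xk.shape[1]:
        raise AnalysisError(
            f"only {Xk.shape[0]} rows for {Xk.shape[1]} retained terms")

    y = design["log_y"].to_numpy(dtype=float)
    fit = sm.OLS(y, Xk).fit()

    is_block = [n.startswith("gen[") or n == "intercept" for n in kept_names]
    p_raw = np.asarray(fit.pvalues, dtype=float)
    p_fdr = np.full_like(p_raw, np.nan)
    family = ~np.array(is_block)
    if family.any():
        p_fdr[family] = fdr_adjust(p_raw[family])
    with np.errstate(divide="ignore"):
        logworth = -np.log10(p_fdr)
    table = pd.DataFrame({
        "term": kept_names,
        "estimate": np.asarray(fit.params, dtype=float),
        "se": np.asarray(fit.bse, dtype=float),
        "p_raw": p_raw,
        "p_fdr": p_fdr,
        "logworth": logworth,
        "significant": p_fdr < fdr_alpha,
    })
    return RegressionResult(table=table, dropped_terms=dropped, n_obs=len(design))


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_table(result: RegressionResult) -> pd.DataFrame:
    """Volcano-plot-ready table: one row per effect term (no intercept or
    block contrasts), sorted by logworth descending."""
    t = result.table
    mask = ~t["term"].str.startswith("gen[") & (t["term"] != "intercept")
    out = t.loc[mask, ["term", "estimate", "logworth", "significant"]]
    return out.sort_values("logworth", ascending=False).reset_index(drop=True)
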