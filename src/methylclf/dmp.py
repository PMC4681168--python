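"""Per-CpG covariate-adjusted differential methylation with moderated t-tests.

Each probe's β values are regressed on group (severe = 1 vs no/mild = 0),
sex, age and six estimated cell-proportion covariates. Residual variances are
shrunk toward an empirical-Bayes prior estimated by moment matching on the
log-variance scale (closed-form trigamma inversion), yielding moderated
t-statistics with augmented degrees of freedom. Probes pass if the
Bonferroni-adjusted p is below α and the raw group mean β difference is at
least the effect-size floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(
    sample_sheet: pd.DataFrame,
    cell_proportions: pd.DataFrame | None = None,
    group_col: str = "group",
    severe_label: str = "severe",
) -> pd.DataFrame:
    """Model matrix: intercept, group, sex, age, plus cell-type covariates."""
    n = len(sample_sheet)
    design = pd.DataFrame(index=sample_sheet.index)
    design["intercept"] = 1.0
    design["group"] = (sample_sheet[group_col].astype(str) == severe_label).astype(float)
    if "sex" in sample_sheet.columns:
        design["sex"] = (sample_sheet["sex"].astype(str) == "M").astype(float)
    if "age_years" in sample_sheet.columns:
        design["age"] = sample_sheet["age_years"].astype(float)
    if cell_proportions is not None:
        cells = cell_proportions.loc[sample_sheet.index]
        for col in cells.columns:
            design[str(col)] = cells[col].astype(float)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    assert len(design) == n
    return design


# ---------------------------------------------------------------------------
# per-probe OLS
# ---------------------------------------------------------------------------

@dataclass
class ProbeFit:
    """OLS results per probe for one design."""

    coefficients: pd.DataFrame    # probes × design columns
    sigma_sq: pd.Series           # residual variance per probe
    df_residual: int
    stdev_unscaled: pd.Series     # sqrt of (X'X)^{-1} diagonal for the group column
    design_columns: list[str]


def fit_probe_models(beta: pd.DataFrame, design: pd.DataFrame) -> ProbeFit:
    """Ordinary least squares of every probe's β profile on the design."""
    if not beta.columns.equals(design.index):
        raise ValueError("β columns and design rows must be aligned")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than covariates")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns for the error message
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(design.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    Y = beta.to_numpy(dtype=float).T  # samples × probes
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y              # p × probes
    resid = Y - X @ B
    df = n - p
    sigma_sq = (resid**2).sum(axis=0) / df
    group_idx = design.columns.get_loc("group")
    stdev_unscaled = np.sqrt(xtx_inv[group_idx, group_idx])
    return ProbeFit(
        coefficients=pd.DataFrame(B.T, index=beta.index, columns=design.columns),
        sigma_sq=pd.Series(sigma_sq, index=beta.index),
        df_residual=df,
        stdev_unscaled=pd.Series(stdev_unscaled, index=beta.index),
        design_columns=list(design.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def moderate_variances(
    sigma_sq: pd.Series | np.ndarray,
    df_residual: int,
    min_probes: int = 10,
) -> tuple[float, float, pd.Series]:
    """Estimate (d₀, s₀²) and return posterior variances s̃².

    Moments of log s² are matched to the theoretical scaled-F (log-chi-square)
    distribution: the spread of log s² in excess of trigamma(d/2) determines
    the prior df d₀ via trigamma inversion, and the location determines s₀².
    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d). With fewer than ``min_probes``
    probes no moderation is applied (d₀ = 0, s̃² = s²).
    """
    s2 = pd.Series(np.asarray(sigma_sq, dtype=float))
    if isinstance(sigma_sq, pd.Series):
        s2.index = sigma_sq.index
    if df_residual < 1:
        raise ValueError("residual df must be ≥ 1")
    if len(s2) < min_probes:
        warnings.warn("fewer than %d probes: skipping variance moderation" % min_probes)
        return 0.0, float(np.median(s2)), s2.copy()

    # floor zero variances at a tiny quantile before the log transform
    positive = s2[s2 > 0]
    floor = positive.quantile(1e-12) if len(positive) else 1e-12
    s2_f = np.maximum(s2.to_numpy(), floor)

    d = float(df_residual)
    z = np.log(s2_f)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: infinite prior df, prior variance is the
        # plain average (exp(e_mean) would carry the log-chi-square bias)
        d0 = np.inf
        s0_sq = float(np.mean(s2_f))
    s2_post = _posterior_variance(s2_f, d, d0, s0_sq)
    return d0, s0_sq, pd.Series(s2_post, index=s2.index)


def _posterior_variance(s2: np.ndarray, d: float, d0: float, s0_sq: float) -> np.ndarray:
    if d0 == 0:
        return np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + d * s2) / (d0 + d)


# ---------------------------------------------------------------------------
# moderated statistics and selection
# ---------------------------------------------------------------------------

def moderated_stats(
    fit: ProbeFit,
    d0: float | None = None,
    s0_sq: float | None = None,
    coef: str = "group",
) -> pd.DataFrame:
    """Moderated t-statistics and (Bonferroni-adjusted) p-values per probe.

    If ``d0``/``s0_sq`` are omitted they are estimated from the fit; forcing
    d₀ = 0 reproduces the ordinary OLS t exactly, d₀ = ∞ uses s₀ alone.
    """
    if d0 is None or s0_sq is None:
        d0, s0_sq, s2_post = moderate_variances(fit.sigma_sq, fit.df_residual)
    else:
        s2_post = pd.Series(
            _posterior_variance(
                fit.sigma_sq.to_numpy(), float(fit.df_residual), d0, s0_sq
            ),
            index=fit.sigma_sq.index,
        )
    b = fit.coefficients[coef]
    se = np.sqrt(s2_post) * fit.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    t = t.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    df_total = d0 + fit.df_residual
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    m = len(b)
    out = pd.DataFrame(
        {
            "coef": b,
            "sigma_sq": fit.sigma_sq,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "p_bonferroni": np.minimum(p * m, 1.0),
        },
        index=fit.coefficients.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_residual"] = fit.df_residual
    return out


def group_mean_difference(beta: pd.DataFrame, group: pd.Series) -> pd.Series:
    """Raw Δβ per probe: mean(severe) − mean(no/mild)."""
    g = np.asarray(group, dtype=float)
    sev = beta.to_numpy()[:, g == 1].mean(axis=1)
    ctl = beta.to_numpy()[:, g == 0].mean(axis=1)
    return pd.Series(sev - ctl, index=beta.index, name="delta_beta")


def select_dmps(
    stats_table: pd.DataFrame,
    delta_beta: pd.Series,
    alpha: float = 0.05,
    min_abs_delta: float = 0.05,
) -> pd.DataFrame:
    """Retain probes with Bonferroni-adjusted p < α and |Δβ| ≥ the floor.

    Result is sorted by raw p ascending; an empty result is valid.
    """
    if not stats_table.index.equals(delta_beta.index):
        delta_beta = delta_beta.reindex(stats_table.index)
    keep = (stats_table["p_bonferroni"] < alpha) & (
        delta_beta.abs() >= min_abs_delta
    )
    out = stats_table.loc[keep].copy()
    out["delta_beta"] = delta_beta.loc[keep]
    out = out.sort_values("p", kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def run_dmp_analysis(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cell_proportions: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_abs_delta: float = 0.05,
    annot: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DMP pass: fit, moderate, test, select.

    Returns (per-probe statistics table, selected DMP table). Annotation
    columns, when provided, are carried onto the selected table.
    """
    design = build_design(sample_sheet, cell_proportions)
    fit = fit_probe_models(beta, design)
    table = moderated_stats(fit)
    delta = group_mean_difference(beta, design["group"])
    table["delta_beta"] = delta
    selected = select_dmps(table.drop(columns="delta_beta"), delta, alpha, min_abs_delta)
    if annot is not None and not selected.empty:
        carry = annot.loc[selected.index, ["chrom", "pos", "gene", "feature", "cpg_context"]]
        selected = selected.join(carry)
    return table, selected


def dmp_table_for_export(selected: pd.DataFrame) -> pd.DataFrame:
    """Arrange a selected-DMP frame in the published-table column layout."""
    cols = {
        "rank": "Rank",
        "p_bonferroni": "Adj. P value",
        "delta_beta": "Delta beta",
        "chrom": "Chr.",
        "pos": "Position",
        "gene": "Gene",
        "feature": "Feature",
        "cpg_context": "CpG context",
    }
    out = selected[[c for c in cols if c in selected.columns]].rename(columns=cols)
    out.insert(1, "DMP", selected.index)
    return out.reset_index(drop=True)
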