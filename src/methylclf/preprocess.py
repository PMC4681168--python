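"""β-value computation, probe filtering, batch adjustment and MDS QC."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# β values
# ---------------------------------------------------------------------------

def compute_beta(
    methylated: pd.DataFrame,
    unmethylated: pd.DataFrame,
    offset: float = 100.0,
) -> pd.DataFrame:
    """Methylation fraction β = M / (M + U + offset), elementwise.

    The offset keeps β strictly below 1 and stabilizes low-intensity probes.
    Negative intensities are rejected.
    """
    if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
        unmethylated.columns
    ):
        raise ValueError("methylated and unmethylated matrices must be aligned")
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be nonnegative")
    if offset <= 0:
        raise ValueError("offset must be positive")
    beta = m / (m + u + offset)
    return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

RULE_NAMES = (
    "detection_p",
    "bead_count",
    "sex_chromosome",
    "non_cg",
    "ambiguous_mapping",
    "snp_at_cg",
)


@dataclass
class FilterReport:
    """Per-rule and total probe removal counts."""

    n_input: int
    removed_by_rule: dict[str, int]
    removed_total: int
    n_surviving: int
    removed_probe_ids: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_by_rule": self.removed_by_rule,
            "removed_total": self.removed_total,
            "n_surviving": self.n_surviving,
        }


def filter_probes(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    detection_p: pd.DataFrame,
    bead_count: pd.DataFrame,
    detection_p_threshold: float = 0.01,
    detection_rule: str = "any",
    bead_min: int = 3,
    bead_sample_fraction: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove probes failing any of the six quality/annotation rules.

    1. detection p ≥ threshold — ``detection_rule='any'`` removes the probe
       if any sample fails (strict reading); ``'median'`` uses the
       across-sample median instead.
    2. bead count < ``bead_min`` in at least ``bead_sample_fraction`` of samples.
    3. probes on chrX / chrY.
    4. non-CG probes.
    5. probes with ambiguous genomic mapping.
    6. probes with a SNP at the probed CG.

    The rules are conjunctive and order-independent: the union of failures is
    removed. Raises if no probes survive.
    """
    for other in (annot, detection_p, bead_count):
        if not beta.index.equals(other.index):
            raise ValueError("inputs must be aligned on probe IDs")
    if detection_rule not in ("any", "median"):
        raise ValueError("detection_rule must be 'any' or 'median'")

    if detection_rule == "any":
        fail_det = (detection_p.to_numpy() >= detection_p_threshold).any(axis=1)
    else:
        fail_det = np.median(detection_p.to_numpy(), axis=1) >= detection_p_threshold
    n_samples = beta.shape[1]
    low_beads = (bead_count.to_numpy() < bead_min).sum(axis=1)
    fail_bead = low_beads >= bead_sample_fraction * n_samples
    fail_sex = annot["chrom"].isin(("chrX", "chrY")).to_numpy()
    fail_noncg = annot["is_noncg"].to_numpy(dtype=bool)
    fail_ambig = annot["is_ambiguous"].to_numpy(dtype=bool)
    fail_snp = annot["has_snp_at_cg"].to_numpy(dtype=bool)

    masks = dict(zip(RULE_NAMES, (fail_det, fail_bead, fail_sex, fail_noncg, fail_ambig, fail_snp)))
    union = np.zeros(len(beta), dtype=bool)
    for m in masks.values():
        union |= m
    surviving = beta.loc[~union]
    if surviving.empty:
        raise ValueError("no probes remain after filtering")
    report = FilterReport(
        n_input=len(beta),
        removed_by_rule={name: int(m.sum()) for name, m in masks.items()},
        removed_total=int(union.sum()),
        n_surviving=len(surviving),
        removed_probe_ids={
            name: beta.index[m].tolist() for name, m in masks.items()
        },
    )
    return surviving, report


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment (parametric location/scale model)
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted per-batch location (γ*) and scale (δ*²) parameters plus priors."""

    batches: list[str]
    gamma_star: pd.DataFrame   # batches × probes
    delta_sq_star: pd.DataFrame
    gamma_bar: pd.Series       # per-batch prior mean
    tau_sq_bar: pd.Series      # per-batch prior variance of γ
    a_prior: pd.Series         # inverse-gamma shape per batch
    b_prior: pd.Series         # inverse-gamma rate per batch


def _design_from_sheet(
    sample_sheet: pd.DataFrame, preserve: tuple[str, ...]
) -> np.ndarray:
    """Covariate design (no intercept) from sample-sheet columns."""
    cols: list[np.ndarray] = []
    for name in preserve:
        col = sample_sheet[name]
        if col.dtype.kind in "if":
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # drop first level as reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(sample_sheet), 0))
    return np.column_stack(cols)


def combat_adjust(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    preserve: tuple[str, ...] = ("group", "sex", "age_years"),
    batch_col: str = "batch_id",
    max_iter: int = 100,
    tol: float = 1e-6,
    preserve_grand_mean: bool = True,
) -> tuple[pd.DataFrame, BatchModel]:
    """Empirical-Bayes location/scale batch adjustment of a β matrix.

    Per probe: standardize against the preserved-covariate fit, shrink
    per-batch means toward a normal prior and per-batch variances toward an
    inverse-gamma prior (hyperparameters by moment matching), then remove the
    shrunken batch effects and back-transform. Biological covariates named in
    ``preserve`` are retained.
    """
    if not beta.columns.equals(sample_sheet.index):
        raise ValueError("β columns and sample sheet rows must be aligned")
    batches = sample_sheet[batch_col].astype(str)
    batch_names = sorted(batches.unique())
    n = beta.shape[1]
    if len(batch_names) == 1:
        model = BatchModel(
            batches=batch_names,
            gamma_star=pd.DataFrame(0.0, index=batch_names, columns=beta.index),
            delta_sq_star=pd.DataFrame(1.0, index=batch_names, columns=beta.index),
            gamma_bar=pd.Series(0.0, index=batch_names),
            tau_sq_bar=pd.Series(0.0, index=batch_names),
            a_prior=pd.Series(np.nan, index=batch_names),
            b_prior=pd.Series(np.nan, index=batch_names),
        )
        return beta.copy(), model

    counts = batches.value_counts()
    singles = counts[counts < 2]
    if not singles.empty:
        raise ValueError(
            f"each batch needs at least 2 samples; offending: {list(singles.index)}"
        )

    batch_design = np.column_stack(
        [(batches == b).to_numpy(dtype=float) for b in batch_names]
    )
    cov_design = _design_from_sheet(sample_sheet, preserve)
    design = np.hstack([batch_design, cov_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "design is rank-deficient: batch is confounded with a preserved covariate"
        )

    Y = beta.to_numpy(dtype=float)  # probes × samples
    # OLS fit of the full (batch + covariate) model
    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # params × probes
    n_batch = len(batch_names)
    batch_counts = np.array([counts[b] for b in batch_names], dtype=float)
    grand_gamma = (batch_counts / n) @ B_hat[:n_batch]  # per-probe grand mean
    stand_mean = grand_gamma[None, :] + (
        cov_design @ B_hat[n_batch:] if cov_design.size else 0.0
    )  # samples × probes
    resid = Y.T - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)  # per probe, 1/n as in the reference model
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd_pooled = np.sqrt(var_pooled)
    Z = (Y.T - stand_mean) / sd_pooled  # samples × probes

    gamma_star = np.empty((n_batch, Y.shape[0]))
    delta_sq_star = np.empty_like(gamma_star)
    gamma_bar = np.empty(n_batch)
    tau_sq_bar = np.empty(n_batch)
    a_prior = np.empty(n_batch)
    b_prior = np.empty(n_batch)

    for bi, b in enumerate(batch_names):
        rows = (batches == b).to_numpy()
        Zb = Z[rows]
        n_b = Zb.shape[0]
        g_hat = Zb.mean(axis=0)
        d_hat = Zb.var(axis=0, ddof=1)
        gamma_bar[bi] = g_hat.mean()
        tau_sq_bar[bi] = g_hat.var(ddof=1)
        m_d = d_hat.mean()
        v_d = d_hat.var(ddof=1)
        v_d = max(v_d, 1e-12)
        a_prior[bi] = (2 * v_d + m_d**2) / v_d
        b_prior[bi] = (m_d * v_d + m_d**3) / v_d
        # iterative EB solution for (γ*, δ²*)
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        tau2 = max(tau_sq_bar[bi], 1e-12)
        for _ in range(max_iter):
            g_new = (tau2 * n_b * g_hat + d_star * gamma_bar[bi]) / (tau2 * n_b + d_star)
            ssq = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_prior[bi] + 0.5 * ssq) / (n_b / 2 + a_prior[bi] - 1)
            change = max(
                np.abs(g_new - g_star).max(initial=0.0),
                np.abs(d_new - d_star).max(initial=0.0),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        gamma_star[bi] = g_star
        delta_sq_star[bi] = np.maximum(d_star, 1e-12)
        Z[rows] = (Zb - g_star[None, :]) / np.sqrt(delta_sq_star[bi])[None, :]

    adjusted = (Z * sd_pooled + stand_mean).T
    if preserve_grand_mean:
        # EB shrinkage leaves a small per-probe offset; re-center so the
        # probe grand mean is untouched (constant shift, leaves batch and
        # covariate contrasts unchanged)
        adjusted += (Y.mean(axis=1) - adjusted.mean(axis=1))[:, None]
    out = pd.DataFrame(adjusted, index=beta.index, columns=beta.columns)
    model = BatchModel(
        batches=batch_names,
        gamma_star=pd.DataFrame(gamma_star, index=batch_names, columns=beta.index),
        delta_sq_star=pd.DataFrame(delta_sq_star, index=batch_names, columns=beta.index),
        gamma_bar=pd.Series(gamma_bar, index=batch_names),
        tau_sq_bar=pd.Series(tau_sq_bar, index=batch_names),
        a_prior=pd.Series(a_prior, index=batch_names),
        b_prior=pd.Series(b_prior, index=batch_names),
    )
    return out, model


# ---------------------------------------------------------------------------
# multidimensional scaling
# ---------------------------------------------------------------------------

def mds_embed(beta: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples from pairwise Euclidean distances.

    Returns samples × n_dims coordinates, centered at the origin.
    """
    n = beta.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for MDS")
    if n_dims >= n:
        raise ValueError("n_dims must be smaller than the number of samples")
    X = beta.to_numpy(dtype=float).T  # samples × probes
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)
    return pd.DataFrame(
        coords, index=beta.columns, columns=[f"MDS{i+1}" for i in range(n_dims)]
    )
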