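"""Relative methylation quantification (PMR) from qPCR Ct values.

Ct values are interpolated to input quantities through a standard curve fit
on a serial dilution of fully methylated control DNA; PMR is the
ratio-of-ratios of target/reference quantities against the fully methylated
control, times 100. Includes the ROC closest-top-left threshold rule and a
Wilcoxon rank-sum test (exact enumeration at small n).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MSSSI_ID, NEG_ID, NTC_ID, STD_PREFIX


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    slope: float        # Ct per log10(quantity); negative
    intercept: float    # Ct at quantity 1
    efficiency: float   # per-cycle amplification factor
    r_squared: float


def fit_standard_curve(
    cts,
    dilution_factor: float = 4.0,
    min_r_squared: float = 0.9,
) -> StandardCurve:
    """Least-squares line of Ct on log10(relative input) for a dilution series.

    ``cts[i]`` is the Ct of the i-th dilution point, at relative quantity
    ``dilution_factor**(-i)``. Refuses fewer than 3 finite points,
    a non-increasing series, or a fit with R² below ``min_r_squared``.
    """
    ct = np.asarray(cts, dtype=float)
    finite = np.isfinite(ct)
    if finite.sum() < 3:
        raise ValueError("need at least 3 dilution points with finite Ct")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    q = dilution_factor ** (-np.arange(ct.size, dtype=float))
    ct, q = ct[finite], q[finite]
    if not np.all(np.diff(ct) > 0):
        raise ValueError("dilution Ct series must increase monotonically")
    x = np.log10(q)
    res = stats.linregress(x, ct)
    r2 = float(res.rvalue**2)
    if r2 < min_r_squared:
        raise ValueError(f"standard curve fit too poor (R² = {r2:.3f})")
    slope = float(res.slope)
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    efficiency = float(10.0 ** (-1.0 / slope))
    return StandardCurve(slope=slope, intercept=float(res.intercept),
                         efficiency=efficiency, r_squared=r2)


def quantity_from_ct(ct, curve: StandardCurve):
    """Invert the standard curve; undetected (NaN) Ct maps to quantity 0."""
    ct_arr = np.asarray(ct, dtype=float)
    q = np.where(
        np.isfinite(ct_arr),
        10.0 ** ((ct_arr - curve.intercept) / curve.slope),
        0.0,
    )
    return float(q) if np.isscalar(ct) or ct_arr.ndim == 0 else q


# ---------------------------------------------------------------------------
# PMR
# ---------------------------------------------------------------------------

#: sentinel for a PMR that cannot be computed (reference failed to amplify)
PMR_UNDEFINED = np.nan


def compute_pmr(
    sample_target: float,
    sample_reference: float,
    control_target: float,
    control_reference: float,
) -> float:
    """PMR = 100 × (target/reference)_sample ÷ (target/reference)_control.

    Target quantity 0 gives PMR 0; a zero reference quantity (sample or
    control) makes the ratio undefined and returns the NaN sentinel.
    """
    if control_reference <= 0 or control_target <= 0:
        warnings.warn("fully methylated control failed to amplify; PMR undefined")
        return PMR_UNDEFINED
    if sample_reference <= 0:
        warnings.warn("sample reference reaction failed; PMR undefined")
        return PMR_UNDEFINED
    if sample_target <= 0:
        return 0.0
    return 100.0 * (sample_target / sample_reference) / (
        control_target / control_reference
    )


def pmr_from_plate(
    plate: pd.DataFrame,
    dilution_factor: float = 4.0,
    control_id: str = MSSSI_ID,
    std_prefix: str = STD_PREFIX,
) -> tuple[pd.DataFrame, dict]:
    """Compute per-sample PMR from a well table (well, sample_id, assay, ct).

    Standard curves are fitted per assay on the ``std_prefix`` dilution
    wells; all Ct values are interpolated to quantities and ratioed against
    the fully methylated control. Samples with an undetected well are
    reported with the sentinel PMR and listed as exclusions.
    """
    required = {"sample_id", "assay", "ct"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate table must contain columns {sorted(required)}")
    is_std = plate["sample_id"].astype(str).str.startswith(std_prefix)
    curves: dict[str, StandardCurve] = {}
    for assay in ("target", "reference"):
        series = plate[is_std & (plate["assay"] == assay)].sort_values("sample_id")
        if series.empty:
            raise ValueError(f"no dilution-series wells for assay '{assay}'")
        curves[assay] = fit_standard_curve(series["ct"].to_numpy(), dilution_factor)

    def qty(sample_id: str, assay: str) -> float:
        sub = plate[(plate["sample_id"] == sample_id) & (plate["assay"] == assay)]
        if sub.empty:
            raise ValueError(f"missing {assay} well for sample {sample_id}")
        return float(np.mean(quantity_from_ct(sub["ct"].to_numpy(), curves[assay])))

    if not (plate["sample_id"] == control_id).any():
        raise ValueError("fully methylated control is missing from the plate")
    ctrl_t = qty(control_id, "target")
    ctrl_r = qty(control_id, "reference")

    sample_ids = [
        s
        for s in plate["sample_id"].unique()
        if not str(s).startswith(std_prefix) and s not in (control_id, NEG_ID, NTC_ID)
    ]
    rows = []
    exclusions = []
    for sid in sample_ids:
        t, r = qty(sid, "target"), qty(sid, "reference")
        undetected = t <= 0 or r <= 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pmr = compute_pmr(t, r, ctrl_t, ctrl_r)
        if undetected:
            exclusions.append(str(sid))
            pmr = PMR_UNDEFINED
        rows.append(
            {"sample_id": sid, "target_quantity": t, "reference_quantity": r, "pmr": pmr}
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    info = {
        "curves": curves,
        "control_ratio": ctrl_t / ctrl_r,
        "excluded_samples": exclusions,
    }
    return out, info


# ---------------------------------------------------------------------------
# thresholding and group tests
# ---------------------------------------------------------------------------

@dataclass
class ThresholdReport:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    direction: str   # 'below' = positive class predicted for values below threshold


def closest_topleft_threshold(values, labels) -> ThresholdReport:
    """Threshold at the ROC point closest to (0, 1).

    Candidate cutpoints are midpoints between sorted distinct values; the
    orientation (positive class above or below the threshold) is the one with
    concordance ≥ ½. Minimizes (1−sens)² + (1−spec)²; ties break toward
    higher specificity.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    pos, neg = v[y == 1], v[y == 0]
    conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
    direction = "above" if conc >= 0.5 else "below"
    auc = conc if conc >= 0.5 else 1.0 - conc

    distinct = np.unique(v)
    if distinct.size == 1:
        warnings.warn("constant scores: degenerate ROC")
        t = float(distinct[0])
        sens = float(np.mean(pos >= t)) if direction == "above" else float(np.mean(pos <= t))
        spec = float(np.mean(neg < t)) if direction == "above" else float(np.mean(neg > t))
        return ThresholdReport(t, sens, spec, float(auc), direction)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None
    for t in candidates:
        if direction == "above":
            sens = float(np.mean(pos > t))
            spec = float(np.mean(neg <= t))
        else:
            sens = float(np.mean(pos < t))
            spec = float(np.mean(neg >= t))
        cost = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        key = (cost, -spec)
        if best is None or key < best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return ThresholdReport(float(t), sens, spec, float(auc), direction)


def wilcoxon_rank_sum(group_a, group_b, exact_max_n: int = 12):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact permutation enumeration of the U statistic when
    n_a + n_b ≤ ``exact_max_n`` (ties handled by midranks within the
    enumeration); otherwise the normal approximation with tie and continuity
    corrections. Returns (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)

    if n_a + n_b <= exact_max_n:
        mu = n_a * n_b / 2.0
        count = 0
        total = 0
        idx = np.arange(n_a + n_b)
        for comb in itertools.combinations(idx, n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        return float(u_obs), count / total

    # normal approximation with tie correction and continuity correction
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    var = n_a * n_b / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return float(u_obs), 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u_obs), float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U of group a over b, ties counted ½."""
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())
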