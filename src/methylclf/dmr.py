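"""Probe-lasso region calling with Stouffer-combined, FDR-adjusted p-values.

A dynamic window ("lasso") is assigned to each probe according to the probe
density of its feature × CpG-context category: sparse categories get wide
windows, dense categories narrow ones, scaled so the aggregate category
radius matches the requested lasso radius. Lassos thrown around significant
probes that capture enough significant neighbors seed regions, nearby
regions are merged, and region p-values are combined across member probes
and adjusted by Benjamini–Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DmrParams:
    lasso_style: str = "max"        # {max, mean, min}
    lasso_radius: float = 2000.0    # bp
    min_sig_probes: int = 2
    min_dmr_sep: float = 1000.0     # bp
    min_dmr_size: float = 0.0       # bp
    adj_p_threshold: float = 0.1
    seed_p_threshold: float = 0.05  # unadjusted per-probe significance
    # quantile of the category nearest-neighbour distances used as the raw
    # radius; 1.0 (the max, capped at lasso_radius) spans every within-
    # category gap so dense probe runs are never split by the lasso
    density_quantile: float = 1.0

    def __post_init__(self) -> None:
        if self.lasso_style not in ("max", "mean", "min"):
            raise ValueError("lasso_style must be one of max/mean/min")
        if self.lasso_radius <= 0 or self.min_dmr_sep <= 0:
            raise ValueError("radii and separations must be positive")
        if not 0 < self.adj_p_threshold < 1:
            raise ValueError("adj_p_threshold must lie in (0, 1)")
        if self.min_sig_probes < 1:
            raise ValueError("min_sig_probes must be ≥ 1")


# ---------------------------------------------------------------------------
# p-value machinery
# ---------------------------------------------------------------------------

def combine_pvalues_stouffer(p_values) -> float:
    """Unweighted Stouffer combination: 1 − Φ(Σ Φ⁻¹(1−pᵢ) / √k)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if (p == 0).any():
        warnings.warn("p = 0 clipped to machine minimum")
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# lasso radii
# ---------------------------------------------------------------------------

def compute_lasso_radii(annot: pd.DataFrame, params: DmrParams) -> pd.Series:
    """Per-probe window radius from feature × CpG-context probe density.

    Each category's raw radius is a quantile of its nearest-neighbor
    distances, capped at ``lasso_radius`` (very sparse categories would
    otherwise crush every dense category toward zero); the capped radii are
    rescaled so that their aggregate (max, mean or min, per ``lasso_style``)
    equals ``lasso_radius``. Categories with fewer than two probes receive
    the global radius, and with ``lasso_style='max'`` no radius exceeds
    ``lasso_radius``.
    """
    if len(annot) == 0:
        return pd.Series(dtype=float, name="lasso_radius")
    feature = annot["feature"].astype(str).fillna("missing")
    context = annot["cpg_context"].astype(str).fillna("missing")
    category = feature + "|" + context

    raw: dict[str, float] = {}
    for cat, sub in annot.groupby(category.to_numpy()):
        if len(sub) < 2:
            raw[cat] = np.nan
            continue
        dists: list[float] = []
        for _, chrom_sub in sub.groupby("chrom"):
            pos = np.sort(chrom_sub["pos"].to_numpy())
            if len(pos) < 2:
                continue
            gaps = np.diff(pos).astype(float)
            nn = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
            dists.extend(nn[np.isfinite(nn)])
        if dists:
            raw[cat] = min(
                float(np.quantile(dists, params.density_quantile)), params.lasso_radius
            )
        else:
            raw[cat] = np.nan

    valid = np.array([v for v in raw.values() if np.isfinite(v) and v > 0])
    if valid.size == 0:
        return pd.Series(params.lasso_radius, index=annot.index, name="lasso_radius")
    agg = {"max": np.max, "mean": np.mean, "min": np.min}[params.lasso_style]
    scale = params.lasso_radius / agg(valid)
    per_cat = {
        cat: (v * scale if np.isfinite(v) and v > 0 else params.lasso_radius)
        for cat, v in raw.items()
    }
    radii = category.map(per_cat).astype(float)
    if params.lasso_style == "max":
        radii = radii.clip(upper=params.lasso_radius)
    radii.name = "lasso_radius"
    radii.index = annot.index
    return radii


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_dmrs(
    probe_stats: pd.DataFrame,
    radii: pd.Series,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Call regions from per-probe p-values and positions.

    ``probe_stats`` needs columns ``chrom``, ``pos`` and ``p`` and must be
    sorted by (chrom, pos). A lasso of the probe's radius is thrown around
    every significant probe (p < ``seed_p_threshold``); lassos capturing at
    least ``min_sig_probes`` significant probes are kept, kept lassos on one
    chromosome whose intervals overlap or lie closer than ``min_dmr_sep``
    merge, region p is Stouffer-combined over member probes and BH-adjusted,
    and regions passing the q and size thresholds are returned.
    """
    params = params or DmrParams()
    for col in ("chrom", "pos", "p"):
        if col not in probe_stats.columns:
            raise ValueError(f"probe_stats must contain column '{col}'")
    grouped = probe_stats.groupby("chrom", sort=False)
    for chrom, sub in grouped:
        if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
            raise ValueError(f"probes on {chrom} are not sorted by position")
    radii = radii.reindex(probe_stats.index)

    candidates: list[dict] = []
    for chrom, sub in grouped:
        pos = sub["pos"].to_numpy(dtype=float)
        p = sub["p"].to_numpy(dtype=float)
        r = radii.loc[sub.index].to_numpy(dtype=float)
        sig = p < params.seed_p_threshold
        sig_pos = pos[sig]
        if sig_pos.size == 0:
            continue
        kept: list[tuple[float, float]] = []
        for i in np.flatnonzero(sig):
            lo, hi = pos[i] - r[i], pos[i] + r[i]
            n_sig_in = int(((sig_pos >= lo) & (sig_pos <= hi)).sum())
            if n_sig_in >= params.min_sig_probes:
                kept.append((lo, hi))
        if not kept:
            continue
        kept.sort()
        merged: list[list[float]] = [list(kept[0])]
        for lo, hi in kept[1:]:
            if lo <= merged[-1][1] + params.min_dmr_sep:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            inside = (pos >= lo) & (pos <= hi)
            members = sub.index[inside]
            member_pos = pos[inside]
            n_sig = int((p[inside] < params.seed_p_threshold).sum())
            if n_sig < params.min_sig_probes:
                continue
            candidates.append(
                {
                    "chrom": chrom,
                    "start": int(member_pos.min()),
                    "end": int(member_pos.max()),
                    "n_probes": int(inside.sum()),
                    "n_significant": n_sig,
                    "probe_ids": list(members),
                    "p_combined": combine_pvalues_stouffer(p[inside]),
                }
            )

    if not candidates:
        return _empty_dmr_frame()
    out = pd.DataFrame(candidates)
    out["q"] = fdr_adjust(out["p_combined"].to_numpy())
    size = out["end"] - out["start"]
    out = out[(out["q"] < params.adj_p_threshold) & (size >= params.min_dmr_size)]
    out = out.sort_values(["p_combined"], kind="mergesort").reset_index(drop=True)
    return out


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "n_probes": pd.Series(dtype=np.int64),
            "n_significant": pd.Series(dtype=np.int64),
            "probe_ids": pd.Series(dtype=object),
            "p_combined": pd.Series(dtype=float),
            "q": pd.Series(dtype=float),
        }
    )


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive region intervals to 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": [f"DMR{i+1}" for i in range(len(dmrs))],
            "score": -np.log10(np.maximum(dmrs["p_combined"], np.finfo(float).tiny)),
        }
    )
    return bed
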