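"""Synthetic cohort and qPCR plate generation with recoverable ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a small "severe" group inside a larger cohort, six-cell-type mixture
profiles, slide-level batch shifts, age and sex covariate effects, planted
differential positions with known signed effect sizes, island-like probe
clustering, and a 4-fold qPCR dilution series. Every artifact is
deterministic given the configuration seed, and each generated object is
paired with the ground truth needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

FEATURE_LABELS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
CPG_CONTEXTS = ("Island", "Shore", "Shelf", "none")
CELL_TYPES = ("CD8T", "CD4T", "Bcell", "NK", "Mono", "Gran")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: sentinel used in plate tables for wells without detectable amplification
UNDETECTED = np.nan


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of a synthetic methylation cohort.

    Defaults mirror the discovery-cohort shape (85 donors, 9 severe) at a
    desk-scale probe count.
    """

    n_samples: int = 85
    n_severe: int = 9
    n_probes: int = 20_000
    n_celltypes: int = 6
    n_planted_dmps: int = 30
    delta_beta_range: tuple[float, float] = (0.06, 0.18)
    n_batches: int = 2
    batch_shift_sd: float = 0.02
    batch_scale_sd: float = 0.0
    noise_sd: float = 0.02
    age_range: tuple[float, float] = (20.0, 70.0)
    age_effect_probes: int = 50
    sex_effect_probes: int = 50
    confound_cells_with_group: bool = False
    island_cluster_size: int = 4
    seed: int = 0
    # annotation / auxiliary knobs
    flag_fraction: float = 0.05
    sex_chrom_fraction: float = 0.05
    island_fraction: float = 0.7
    n_discriminating: int = 600
    discriminating_spread: float = 0.3
    qc_fail_fraction: float = 0.002
    age_slope: float = 0.002
    sex_offset: float = 0.05
    n_planted_clusters: int = 0
    planted_sign: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 < self.n_severe < self.n_samples:
            raise ValueError("need 0 < n_severe < n_samples")
        if self.n_probes < 0:
            raise ValueError("n_probes must be nonnegative")
        for name in ("n_celltypes", "n_batches", "island_cluster_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.delta_beta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("delta_beta_range must lie strictly inside (0, 1)")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.planted_sign not in (None, -1, 1):
            raise ValueError("planted_sign must be None, -1 or +1")


@dataclass
class PlateConfig:
    """Parameters of a synthetic MethyLight qPCR plate."""

    n_samples_per_group: int = 10
    true_pmr_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"severe": 5.0, "no/mild": 25.0}
    )
    dilution_factor: float = 4.0
    n_dilution_points: int = 5
    ct_noise_sd: float = 0.0
    efficiency: float = 2.0
    seed: int = 0
    target_intercept: float = 24.0
    reference_intercept: float = 22.0
    n_undetected_samples: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")
        if self.n_samples_per_group <= 0 or self.n_dilution_points < 2:
            raise ValueError("counts must be positive (≥2 dilution points)")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    planted_dmps: pd.Series          # probe_id -> signed true Δβ
    cell_proportions: pd.DataFrame   # samples × cell types, rows sum to 1
    batch_shifts: pd.DataFrame       # batches × probes location offsets
    group_labels: pd.Series          # sample_id -> 0/1 (1 = severe)
    age_probe_ids: pd.Index
    sex_probe_ids: pd.Index
    planted_cluster_ids: list[list[str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_dmps": self.planted_dmps.to_dict(),
            "cell_proportions": self.cell_proportions.to_dict(orient="index"),
            "batch_shifts": {b: row.tolist() for b, row in self.batch_shifts.iterrows()},
            "group_labels": self.group_labels.to_dict(),
            "age_probe_ids": list(self.age_probe_ids),
            "sex_probe_ids": list(self.sex_probe_ids),
            "planted_cluster_ids": self.planted_cluster_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class PlateTruth:
    """Ground truth for a simulated qPCR plate."""

    true_pmr: pd.Series       # sample_id -> PMR on the 0–100 scale
    group_labels: pd.Series   # sample_id -> group name
    efficiency: float
    undetected_samples: list[str] = field(default_factory=list)


@dataclass
class QcTables:
    """Per-probe, per-sample array QC measurements."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame


@dataclass
class CellReference:
    """Reference methylation profiles of purified leukocyte populations.

    ``values`` covers all probes; ``discriminating`` names the designated
    subset on which the cell types are well separated (between-type spread
    of at least ``CohortConfig.discriminating_spread``).
    """

    values: pd.DataFrame          # probes × cell types
    discriminating: pd.Index

    @property
    def discriminating_values(self) -> pd.DataFrame:
        return self.values.loc[self.discriminating]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _empty_annotation() -> pd.DataFrame:
    cols = ["chrom", "pos", "gene", "feature", "cpg_context",
            "is_noncg", "is_ambiguous", "has_snp_at_cg"]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    for c in ("is_noncg", "is_ambiguous", "has_snp_at_cg"):
        df[c] = df[c].astype(bool)
    df["pos"] = df["pos"].astype(np.int64)
    df.index.name = "probe_id"
    return df


def generate_annotation(config: CohortConfig) -> pd.DataFrame:
    """Emit a manifest-like probe annotation table.

    Probes are laid out in island-like clusters (within-cluster spacing
    ≤ 500 bp, between-cluster gaps ≥ 5 kb) interleaved with singleton
    open-sea probes; a configurable fraction carries each removal flag.
    """
    n = config.n_probes
    if n == 0:
        return _empty_annotation()
    rng = np.random.default_rng([config.seed, 0])

    chroms: list[str] = []
    positions: list[int] = []
    contexts: list[str] = []
    features: list[str] = []
    genes: list[str] = []

    chrom_cursor: dict[str, int] = {}
    gene_counter = 0
    placed = 0
    while placed < n:
        in_island = rng.random() < config.island_fraction
        size = min(config.island_cluster_size if in_island else 1, n - placed)
        if rng.random() < config.sex_chrom_fraction:
            chrom = "chrX" if rng.random() < 0.7 else "chrY"
        else:
            chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
        pos = chrom_cursor.get(chrom, 1_000_000)
        pos += int(rng.integers(5_000, 50_000))  # ≥ 5 kb between clusters
        feature = FEATURE_LABELS[rng.integers(len(FEATURE_LABELS))]
        if feature == "IGR":
            gene = "-"
        else:
            gene_counter += 1
            gene = f"GENE{gene_counter:05d}"
        context = "Island" if in_island else CPG_CONTEXTS[1 + rng.integers(3)]
        for j in range(size):
            chroms.append(chrom)
            positions.append(pos)
            contexts.append(context)
            features.append(feature)
            genes.append(gene)
            pos += int(rng.integers(50, 501))  # ≤ 500 bp within cluster
        chrom_cursor[chrom] = pos
        placed += size

    annot = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "gene": genes,
            "feature": features,
            "cpg_context": contexts,
            "is_noncg": rng.random(n) < config.flag_fraction,
            "is_ambiguous": rng.random(n) < config.flag_fraction,
            "has_snp_at_cg": rng.random(n) < config.flag_fraction,
        },
    )
    annot = annot.sort_values(["chrom", "pos"], kind="mergesort")
    annot.index = pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")
    return annot


# ---------------------------------------------------------------------------
# cell-type reference
# ---------------------------------------------------------------------------

def _clean_probe_mask(annot: pd.DataFrame) -> pd.Series:
    """Probes that survive all annotation-based filters."""
    return (
        ~annot["chrom"].isin(("chrX", "chrY"))
        & ~annot["is_noncg"]
        & ~annot["is_ambiguous"]
        & ~annot["has_snp_at_cg"]
    )


def generate_cell_reference(annot: pd.DataFrame, config: CohortConfig) -> CellReference:
    """Build per-cell-type reference β profiles.

    Non-discriminating probes share one (bimodal) value across cell types, so
    mixture weights leave them untouched; the designated discriminating
    subset alternates high/low states between types so that every pair of
    profiles differs by at least ``discriminating_spread`` on some probe.
    """
    if len(annot) == 0:
        raise ValueError("annotation must be nonempty")
    rng = np.random.default_rng([config.seed, 1])
    k = config.n_celltypes
    cell_names = list(CELL_TYPES[:k]) if k <= len(CELL_TYPES) else [
        f"Cell{i+1}" for i in range(k)
    ]
    n = len(annot)

    # bimodal base: peaks near 0 and 1 with a mid-methylation shoulder
    low = rng.beta(2.0, 18.0, size=n)
    high = rng.beta(18.0, 2.0, size=n)
    mid = rng.uniform(0.25, 0.75, size=n)
    comp = rng.random(n)
    base = np.where(comp < 0.4, low, np.where(comp < 0.8, high, mid))
    values = np.tile(base[:, None], (1, k)).astype(float)

    clean = _clean_probe_mask(annot)
    pool = annot.index[clean.to_numpy()]
    n_disc = min(config.n_discriminating, len(pool)) if k > 1 else 0
    disc = pd.Index(rng.choice(pool, size=n_disc, replace=False)) if n_disc else pd.Index([])

    if n_disc:
        half = config.discriminating_spread / 2.0
        lo_c, hi_c = 0.5 - half - 0.15, 0.5 + half + 0.15  # centers ≥ spread apart
        lo_c = max(lo_c, 0.03)
        hi_c = min(hi_c, 0.97)
        idx = annot.index.get_indexer(disc)
        # first 2^k - 2 probes follow the binary pattern so every pair of
        # cell types is separated on at least one probe
        patterns = []
        for code in range(1, 2**k - 1):
            patterns.append([(code >> t) & 1 for t in range(k)])
        for j, row in enumerate(idx):
            if j < len(patterns):
                pat = np.asarray(patterns[j], dtype=bool)
            else:
                pat = rng.random(k) < 0.5
                if pat.all() or not pat.any():
                    pat[rng.integers(k)] = not pat[0]
            vals = np.where(pat, hi_c, lo_c) + rng.normal(0.0, 0.01, size=k)
            values[row] = np.clip(vals, 0.0, 1.0)

    ref = pd.DataFrame(values, index=annot.index, columns=cell_names)
    return CellReference(values=ref, discriminating=disc)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _assign_batches(n: int, n_batches: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([f"batch{(i % n_batches) + 1}" for i in range(n)], dtype=object)
    rng.shuffle(base)
    return base


def generate_cohort(
    config: CohortConfig,
    reference: CellReference,
    annot: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, QcTables, GroundTruth]:
    """Simulate a β matrix, sample sheet, QC tables and ground truth.

    Sample β = clip[ mixture-weighted reference + planted group effect
    (severe only) + age slope + sex offset + batch shift + Gaussian noise ].
    Planted, age- and sex-effect probes are drawn from the pool that
    survives all probe filters; a config whose planted probes cannot avoid
    flagged probes is rejected.
    """
    if not reference.values.index.equals(annot.index):
        raise ValueError("reference and annotation probe IDs must match")
    rng = np.random.default_rng([config.seed, 2])
    n_s, n_p = config.n_samples, config.n_probes
    k = reference.values.shape[1]
    sample_ids = [f"S{i:03d}" for i in range(1, n_s + 1)]
    probe_ids = annot.index

    # groups / covariates
    y = np.zeros(n_s, dtype=int)
    y[rng.choice(n_s, size=config.n_severe, replace=False)] = 1
    sexes = np.where(rng.random(n_s) < 0.5, "M", "F")
    ages = rng.uniform(*config.age_range, size=n_s).round(1)
    batches = _assign_batches(n_s, config.n_batches, rng)

    # cell-mixture weights
    alpha = np.full(k, 5.0)
    w = rng.dirichlet(alpha, size=n_s)
    if config.confound_cells_with_group and k > 1:
        alpha_sev = alpha.copy()
        alpha_sev[0] *= 3.0  # severe donors skewed toward the first cell type
        w_sev = rng.dirichlet(alpha_sev, size=int(y.sum()))
        w[y == 1] = w_sev

    beta = reference.values.to_numpy() @ w.T  # probes × samples

    # pools of probes eligible for planted effects: must survive filters and
    # stay out of the deconvolution's discriminating subset
    clean = _clean_probe_mask(annot).to_numpy()
    eligible = clean.copy()
    eligible[annot.index.get_indexer(reference.discriminating)] = False
    base_val = reference.values.to_numpy()[:, 0]
    headroom = (base_val > 0.2) & (base_val < 0.8)
    pool = np.flatnonzero(eligible & headroom)
    rng.shuffle(pool)
    pool = list(pool)

    def take(count: int, what: str) -> np.ndarray:
        if len(pool) < count:
            raise ValueError(
                f"cannot place {count} {what}: only {len(pool)} clean probes "
                "free of filter flags remain"
            )
        out = np.array([pool.pop() for _ in range(count)], dtype=int)
        return out

    # planted DMPs, optionally as whole island clusters
    lo, hi = config.delta_beta_range
    planted_rows: list[int] = []
    planted_deltas: list[float] = []
    cluster_ids: list[list[str]] = []
    if config.n_planted_clusters > 0:
        # whole island clusters of clean probes sharing one signed Δβ; members
        # need headroom only in the direction of the effect
        clean_set = set(np.flatnonzero(eligible))
        island = annot["cpg_context"].to_numpy() == "Island"
        runs: dict[int, list[int]] = {}
        run_id, prev = 0, None
        positions = annot["pos"].to_numpy()
        chrom_arr = annot["chrom"].to_numpy()
        for i in range(len(annot)):
            if prev is None or chrom_arr[i] != chrom_arr[prev] or positions[i] - positions[prev] > 500:
                run_id += 1
            runs.setdefault(run_id, []).append(i)
            prev = i
        for _ in range(config.n_planted_clusters):
            sign = config.planted_sign if config.planted_sign is not None else (
                -1 if rng.random() < 0.5 else 1
            )
            if sign < 0:
                fits = base_val > hi + 0.01
            else:
                fits = base_val < 1.0 - hi - 0.01
            usable = [
                rows for rows in runs.values()
                if len(rows) >= config.island_cluster_size
                and all(island[r] and r in clean_set and fits[r] for r in rows)
                and not any(r in planted_rows for r in rows)
            ]
            if not usable:
                raise ValueError("not enough clean island clusters to plant")
            rows = usable[int(rng.integers(len(usable)))][: config.island_cluster_size]
            delta = sign * rng.uniform(lo, hi)
            for r in rows:
                planted_rows.append(r)
                planted_deltas.append(delta)
                if r in pool:
                    pool.remove(r)
            cluster_ids.append([probe_ids[r] for r in rows])
    n_single = config.n_planted_dmps - len(planted_rows)
    if n_single < 0:
        raise ValueError("planted clusters exceed n_planted_dmps")
    if n_single:
        rows = take(n_single, "planted DMPs")
        mags = rng.uniform(lo, hi, size=n_single)
        if config.planted_sign is None:
            signs = np.where(rng.random(n_single) < 0.5, -1.0, 1.0)
        else:
            signs = np.full(n_single, float(config.planted_sign))
        planted_rows.extend(rows.tolist())
        planted_deltas.extend((signs * mags).tolist())

    age_rows = take(config.age_effect_probes, "age-effect probes")
    sex_rows = take(config.sex_effect_probes, "sex-effect probes")

    planted_rows_arr = np.asarray(planted_rows, dtype=int)
    planted_deltas_arr = np.asarray(planted_deltas, dtype=float)
    if len(planted_rows_arr):
        beta[np.ix_(planted_rows_arr, np.flatnonzero(y == 1))] += planted_deltas_arr[:, None]

    beta[age_rows] += config.age_slope * (ages - ages.mean())[None, :]
    beta[np.ix_(sex_rows, np.flatnonzero(sexes == "M"))] += config.sex_offset

    # batch structure: per-batch per-probe location shift, per-batch noise scale
    batch_names = sorted(set(batches))
    shifts = pd.DataFrame(
        rng.normal(0.0, config.batch_shift_sd, size=(len(batch_names), n_p)),
        index=batch_names,
        columns=probe_ids,
    )
    scales = {
        b: float(np.exp(rng.normal(0.0, config.batch_scale_sd))) if config.batch_scale_sd else 1.0
        for b in batch_names
    }
    for b in batch_names:
        cols = np.flatnonzero(batches == b)
        beta[:, cols] += shifts.loc[b].to_numpy()[:, None]
        if config.noise_sd > 0:
            beta[:, cols] += rng.normal(0.0, config.noise_sd * scales[b], size=(n_p, len(cols)))

    beta = np.clip(beta, 0.001, 0.999)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)

    sheet = pd.DataFrame(
        {
            "group": np.where(y == 1, "severe", "no/mild"),
            "sex": sexes,
            "age_years": ages,
            "batch_id": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    qc = _generate_qc(
        config, rng, probe_ids, sample_ids,
        protected=np.concatenate([planted_rows_arr, age_rows, sex_rows,
                                  annot.index.get_indexer(reference.discriminating)]),
    )

    truth = GroundTruth(
        planted_dmps=pd.Series(planted_deltas_arr, index=probe_ids[planted_rows_arr]),
        cell_proportions=pd.DataFrame(w, index=sample_ids, columns=reference.values.columns),
        batch_shifts=shifts,
        group_labels=pd.Series(y, index=sample_ids),
        age_probe_ids=probe_ids[age_rows],
        sex_probe_ids=probe_ids[sex_rows],
        planted_cluster_ids=cluster_ids,
    )
    return beta_df, sheet, qc, truth


def _generate_qc(
    config: CohortConfig,
    rng: np.random.Generator,
    probe_ids: pd.Index,
    sample_ids: list[str],
    protected: np.ndarray,
) -> QcTables:
    n_p, n_s = len(probe_ids), len(sample_ids)
    det = rng.uniform(0.0, 0.005, size=(n_p, n_s))
    beads = rng.integers(8, 31, size=(n_p, n_s))

    n_fail = int(round(config.qc_fail_fraction * n_p))
    if n_fail:
        candidates = np.setdiff1d(np.arange(n_p), protected)
        fail = rng.choice(candidates, size=min(n_fail, len(candidates)), replace=False)
        half = len(fail) // 2
        # detection failures: majority of samples fail so both rule readings remove them
        n_bad = max(1, int(np.ceil(0.6 * n_s)))
        for r in fail[:half] if half else fail[:0]:
            cols = rng.choice(n_s, size=n_bad, replace=False)
            det[r, cols] = rng.uniform(0.05, 0.5, size=n_bad)
        # bead failures: bead count < 3 in ≥ 5 % of samples
        n_low = max(1, int(np.ceil(0.10 * n_s)))
        for r in fail[half:]:
            cols = rng.choice(n_s, size=n_low, replace=False)
            beads[r, cols] = rng.integers(0, 3, size=n_low)

    det_df = pd.DataFrame(det, index=probe_ids, columns=sample_ids)
    bead_df = pd.DataFrame(beads, index=probe_ids, columns=sample_ids)
    return QcTables(detection_p=det_df, bead_count=bead_df)


def simulate_cohort(config: CohortConfig):
    """Convenience wrapper: annotation + reference + cohort in one call."""
    annot = generate_annotation(config)
    ref = generate_cell_reference(annot, config)
    beta, sheet, qc, truth = generate_cohort(config, ref, annot)
    return beta, sheet, annot, qc, ref, truth


# ---------------------------------------------------------------------------
# MethyLight plate
# ---------------------------------------------------------------------------

MSSSI_ID = "MSSSI"
NEG_ID = "NEG_CONTROL"
NTC_ID = "NTC"
STD_PREFIX = "STD"


def _ct(quantity: float, intercept: float, efficiency: float) -> float:
    if quantity <= 0:
        return UNDETECTED
    return intercept - np.log(quantity) / np.log(efficiency)


def generate_methylight_plate(config: PlateConfig) -> tuple[pd.DataFrame, PlateTruth]:
    """Simulate a qPCR plate: samples, controls and a dilution series.

    Ct = intercept − log(quantity)/log(efficiency) + noise, for a target
    (methylation-specific) and a reference (input-normalization) reaction.
    Includes the fully methylated control (true PMR = 100), an unmethylated
    negative control (target never amplifies), a non-template control, and a
    ``dilution_factor``-fold dilution series of the methylated standard for
    both assays.
    """
    rng = np.random.default_rng([config.seed, 3])
    rows: list[dict] = []
    truth_pmr: dict[str, float] = {}
    truth_group: dict[str, str] = {}

    def add(sample_id: str, assay: str, qty: float, intercept: float) -> None:
        ct = _ct(qty, intercept, config.efficiency)
        if np.isfinite(ct) and config.ct_noise_sd > 0:
            ct += rng.normal(0.0, config.ct_noise_sd)
        rows.append({"sample_id": sample_id, "assay": assay, "ct": ct})

    # dilution series (quantity 1, 1/f, 1/f², ...) for both assays
    for i in range(config.n_dilution_points):
        qty = config.dilution_factor ** (-i)
        sid = f"{STD_PREFIX}{i + 1}"
        add(sid, "target", qty, config.target_intercept)
        add(sid, "reference", qty, config.reference_intercept)

    # controls
    ctrl_qty = 0.8
    add(MSSSI_ID, "target", ctrl_qty, config.target_intercept)
    add(MSSSI_ID, "reference", ctrl_qty, config.reference_intercept)
    add(NEG_ID, "target", 0.0, config.target_intercept)
    add(NEG_ID, "reference", ctrl_qty, config.reference_intercept)
    add(NTC_ID, "target", 0.0, config.target_intercept)
    add(NTC_ID, "reference", 0.0, config.reference_intercept)

    # samples
    undetected: list[str] = []
    counter = 0
    for group, pmr in config.true_pmr_by_group.items():
        for _ in range(config.n_samples_per_group):
            counter += 1
            sid = f"P{counter:03d}"
            ref_qty = rng.uniform(0.2, 1.0)
            tgt_qty = (pmr / 100.0) * ref_qty  # control target/ref ratio is 1
            if len(undetected) < config.n_undetected_samples:
                undetected.append(sid)
                add(sid, "target", 0.0, config.target_intercept)
            else:
                add(sid, "target", tgt_qty, config.target_intercept)
            add(sid, "reference", ref_qty, config.reference_intercept)
            truth_pmr[sid] = float(pmr)
            truth_group[sid] = group

    plate = pd.DataFrame(rows)
    plate.insert(0, "well", [f"W{i + 1:03d}" for i in range(len(plate))])
    truth = PlateTruth(
        true_pmr=pd.Series(truth_pmr),
        group_labels=pd.Series(truth_group),
        efficiency=config.efficiency,
        undetected_samples=undetected,
    )
    return plate, truth


# ---------------------------------------------------------------------------
# writers (plain-text external formats)
# ---------------------------------------------------------------------------

def write_cohort(
    outdir: str | Path,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annot: pd.DataFrame,
    qc: QcTables,
    reference: CellReference,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the cohort in the plain-text exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "annotation": outdir / "annotation.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "bead_count": outdir / "bead_count.tsv",
        "cell_reference": outdir / "cell_reference.tsv",
    }
    beta.to_csv(paths["beta"], sep="\t")
    sheet.to_csv(paths["sample_sheet"])
    annot.to_csv(paths["annotation"], sep="\t")
    qc.detection_p.to_csv(paths["detection_p"], sep="\t")
    qc.bead_count.to_csv(paths["bead_count"], sep="\t")
    reference.discriminating_values.to_csv(paths["cell_reference"], sep="\t")
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        truth.to_json(paths["ground_truth"])
    return paths


def config_to_dict(config) -> dict:
    return asdict(config)
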