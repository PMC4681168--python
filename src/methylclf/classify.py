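"""Nearest-shrunken-centroid classification with nested LOOCV and ROC/AUC.

Feature (DMP) selection is repeated inside every leave-one-out fold so no
information from the held-out sample leaks into the classifier; held-out
scores are pooled into a single ROC whose AUC gets a DeLong confidence
interval. Probe selection recurrence across folds supports the final
recurrence-ranked marker table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dmp as dmp_mod

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nearest shrunken centroid
# ---------------------------------------------------------------------------

@dataclass
class NscModel:
    probe_ids: pd.Index
    classes: np.ndarray                 # sorted class labels
    overall_centroid: np.ndarray        # per probe
    class_centroids: np.ndarray         # probes × classes (shrunken)
    s: np.ndarray                       # pooled within-class sd per probe
    s0: float                           # median of s
    delta: float
    n_k: np.ndarray
    priors: np.ndarray
    d_ik: np.ndarray                    # probes × classes, unshrunken
    d_prime: np.ndarray                 # probes × classes, soft-thresholded


def train_nsc(
    X: pd.DataFrame,
    y,
    delta: float = 1.0,
    priors: np.ndarray | None = None,
    m_convention: str = "minus",
) -> NscModel:
    """Fit a nearest-shrunken-centroid model on samples × probes data.

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s₀)) with m_k = √(1/n_k − 1/n)
    (``m_convention='plus'`` uses √(1/n_k + 1/n)); the differences are
    soft-thresholded at ``delta`` and centroids reconstructed as
    x̄′_ik = x̄_i + m_k (s_i + s₀) d′_ik.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    V = X.to_numpy(dtype=float)
    n, p = V.shape
    if p < 1:
        raise ValueError("need at least one probe")
    n_k = np.array([(y == c).sum() for c in classes], dtype=float)
    if priors is None:
        priors = n_k / n
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()

    overall = V.mean(axis=0)
    cents = np.column_stack([V[y == c].mean(axis=0) for c in classes])  # p × K
    # pooled within-class variance
    ss = np.zeros(p)
    for j, c in enumerate(classes):
        ss += ((V[y == c] - cents[:, j][None, :]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - classes.size))
    s0 = float(np.median(s))

    if m_convention == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    elif m_convention == "plus":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    else:
        raise ValueError("m_convention must be 'minus' or 'plus'")

    denom = (s + s0)[:, None] * m_k[None, :]
    d_ik = (cents - overall[:, None]) / denom
    d_prime = np.sign(d_ik) * np.maximum(np.abs(d_ik) - delta, 0.0)
    shrunk = overall[:, None] + denom * d_prime

    return NscModel(
        probe_ids=X.columns,
        classes=classes,
        overall_centroid=overall,
        class_centroids=shrunk,
        s=s,
        s0=s0,
        delta=float(delta),
        n_k=n_k.astype(int),
        priors=priors,
        d_ik=d_ik,
        d_prime=d_prime,
    )


def nsc_discriminant(model: NscModel, X: pd.DataFrame) -> np.ndarray:
    """δ_k(x) = Σ_i (x_i − x̄′_ik)² / (s_i + s₀)² − 2 log π_k, rows × classes."""
    if isinstance(X, pd.DataFrame):
        missing = model.probe_ids.difference(X.columns)
        if len(missing):
            raise ValueError(f"missing probe values for {list(missing)[:5]} ...")
        V = X[model.probe_ids].to_numpy(dtype=float)
    else:
        V = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(V).all():
        raise ValueError("missing probe values in prediction input")
    scale = (model.s + model.s0) ** 2
    deltas = np.empty((V.shape[0], model.classes.size))
    for j in range(model.classes.size):
        deltas[:, j] = (((V - model.class_centroids[:, j][None, :]) ** 2) / scale).sum(
            axis=1
        ) - 2.0 * np.log(model.priors[j])
    return deltas


def predict_nsc(
    model: NscModel, X: pd.DataFrame, positive_class=1
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class and positive-class posterior score per row.

    Score = softmax of −δ_k/2 evaluated for the positive class.
    """
    deltas = nsc_discriminant(model, X)
    pred = model.classes[np.argmin(deltas, axis=1)]
    logw = -deltas / 2.0
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    post = w / w.sum(axis=1, keepdims=True)
    pos_idx = int(np.flatnonzero(model.classes == positive_class)[0])
    return pred, post[:, pos_idx]


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval
# ---------------------------------------------------------------------------

def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) over descending score thresholds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((1 - y).sum(), 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_auc(scores, labels, ci_level: float = 0.95):
    """Pooled AUC (Mann–Whitney concordance, ties ½) with DeLong CI.

    Returns (roc_points, auc, (lo, hi)).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # AUC from the exact pairwise concordance count (half-integers are exact)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float(wins + 0.5 * ties) / (pos.size * neg.size)
    # placement values (structural components for the DeLong variance)
    v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
    v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    var = s10 / pos.size + s01 / neg.size
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return roc_points(s, y), auc, ci


# ---------------------------------------------------------------------------
# nested leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvReport:
    records: pd.DataFrame          # sample_id, truth, predicted, score, n_dmps
    roc: pd.DataFrame
    auc: float
    auc_ci: tuple[float, float]
    recurrence: pd.Series          # probe_id -> number of folds selecting it
    n_iterations: int
    zero_dmp_folds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "zero_dmp_folds": self.zero_dmp_folds,
            "records": self.records.to_dict(orient="records"),
            "recurrence": self.recurrence.to_dict(),
        }


def loocv_evaluate(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cell_proportions: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_abs_delta: float = 0.05,
    nsc_delta: float = 1.0,
    priors: np.ndarray | None = None,
    max_features: int | None = None,
) -> LoocvReport:
    """Nested LOOCV: re-select DMPs inside every fold, score the held-out sample.

    In each of n iterations the held-out sample is removed, the moderated-t
    DMP analysis is rerun on the remaining n−1 samples (cell-proportion
    covariates are taken as given), significant DMPs are ranked by p, an NSC
    model with shrinkage ``nsc_delta`` is trained on them, and the held-out
    sample is scored. Folds selecting zero DMPs score the held-out sample at
    the training prior of the severe class (and are logged). Held-out scores
    are pooled into one ROC with a DeLong AUC CI; per-probe recurrence counts
    the folds in which each probe was selected.
    """
    groups = (sample_sheet["group"].astype(str) == "severe").astype(int)
    if groups.sum() < 2 or (1 - groups).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    sample_ids = list(beta.columns)
    recurrence: dict[str, int] = {}
    rows = []
    zero_folds: list[str] = []
    # constant fallback score for zero-DMP folds: the cohort-level class
    # prior (or the user-supplied one). Using the training-fold prior instead
    # would anti-correlate with the held-out label (removing a severe sample
    # lowers it), turning an uninformative fold into a perverse signal.
    if priors is not None:
        fallback_score = float(np.asarray(priors, dtype=float)[1])
    else:
        fallback_score = float(groups.mean())

    for sid in sample_ids:
        train_ids = [s for s in sample_ids if s != sid]
        beta_tr = beta[train_ids]
        sheet_tr = sample_sheet.loc[train_ids]
        cells_tr = cell_proportions.loc[train_ids] if cell_proportions is not None else None
        _, selected = dmp_mod.run_dmp_analysis(
            beta_tr, sheet_tr, cells_tr, alpha=alpha, min_abs_delta=min_abs_delta
        )
        if max_features is not None:
            selected = selected.head(max_features)
        truth = int(groups.loc[sid])
        y_tr = groups.loc[train_ids].to_numpy()
        if selected.empty:
            zero_folds.append(sid)
            rows.append(
                {"sample_id": sid, "truth": truth,
                 "predicted": int(fallback_score >= 0.5),
                 "score": fallback_score, "n_dmps": 0}
            )
            continue
        probes = selected.index
        for pid in probes:
            recurrence[pid] = recurrence.get(pid, 0) + 1
        X_tr = beta_tr.loc[probes].T
        model = train_nsc(X_tr, y_tr, delta=nsc_delta, priors=priors)
        x_new = beta.loc[probes, [sid]].T
        pred, score = predict_nsc(model, x_new)
        rows.append(
            {"sample_id": sid, "truth": truth, "predicted": int(pred[0]),
             "score": float(score[0]), "n_dmps": int(len(probes))}
        )

    records = pd.DataFrame(rows)
    roc, auc, ci = roc_auc(records["score"], records["truth"])
    if zero_folds:
        logger.info("%d folds selected zero DMPs; scored at the prior", len(zero_folds))
    rec = pd.Series(recurrence, dtype=int).sort_values(ascending=False)
    rec.index.name = "probe_id"
    return LoocvReport(
        records=records,
        roc=roc,
        auc=auc,
        auc_ci=ci,
        recurrence=rec,
        n_iterations=len(sample_ids),
        zero_dmp_folds=zero_folds,
    )


def rank_dmp_recurrence(
    report: LoocvReport, full_data_dmps: pd.DataFrame
) -> pd.DataFrame:
    """Rank the full-data DMPs by LOOCV recurrence, ties by |Δβ| descending."""
    if full_data_dmps.empty:
        return pd.DataFrame(
            columns=["probe_id", "recurrence", "delta_beta", "p_bonferroni"]
        )
    out = full_data_dmps.copy()
    out["recurrence"] = [
        int(report.recurrence.get(pid, 0)) for pid in out.index
    ]
    out["abs_delta"] = out["delta_beta"].abs()
    out = out.sort_values(
        ["recurrence", "abs_delta"], ascending=[False, False], kind="mergesort"
    ).drop(columns="abs_delta")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
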