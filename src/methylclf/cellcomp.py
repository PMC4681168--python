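"""Reference-based leukocyte deconvolution by constrained regression.

Each sample's β profile over a set of discriminating probes is regressed on
purified-cell reference profiles under a nonnegativity constraint. No
sum-to-one constraint is imposed: the estimates are relative proportions and
enter downstream models as six separate covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .synthetic import CellReference


def select_discriminating_probes(reference: pd.DataFrame, n: int = 600) -> pd.Index:
    """Top-``n`` probes by between-cell-type spread of the reference profiles.

    With one profile per cell type there are no within-type replicates, so
    the between-type variance of the reference row plays the role of the
    usual F statistic.
    """
    spread = reference.var(axis=1, ddof=0)
    return spread.sort_values(ascending=False).head(n).index


def estimate_cell_proportions(
    beta: pd.DataFrame,
    reference: CellReference | pd.DataFrame,
    max_condition: float = 1e8,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions ŵ = argmin ‖b − Rw‖², w ≥ 0.

    ``reference`` may be a :class:`CellReference` (its discriminating subset
    is used) or a plain probes × cell-types frame. Probes are aligned by ID;
    a rank-deficient reference is refused with its condition number.
    """
    if isinstance(reference, CellReference):
        ref = reference.discriminating_values
    else:
        ref = reference
    common = ref.index.intersection(beta.index)
    if len(common) < ref.shape[1]:
        raise ValueError(
            f"need at least {ref.shape[1]} shared discriminating probes, got {len(common)}"
        )
    R = ref.loc[common].to_numpy(dtype=float)
    cond = np.linalg.cond(R)
    if np.linalg.matrix_rank(R) < R.shape[1] or cond > max_condition:
        raise ValueError(
            f"reference is rank-deficient or ill-conditioned (condition number {cond:.3g})"
        )
    B = beta.loc[common].to_numpy(dtype=float)
    est = np.empty((beta.shape[1], R.shape[1]))
    for j in range(beta.shape[1]):
        est[j], _ = nnls(R, B[:, j])
    return pd.DataFrame(est, index=beta.columns, columns=ref.columns)
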