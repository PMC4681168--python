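import numpy as np
import pandas as pd
import pytest

from methylclf import synthetic as syn
from methylclf import cellcomp, preprocess


@pytest.fixture(scope="session")
def small_config():
    return syn.CohortConfig(
        n_samples=40,
        n_severe=6,
        n_probes=3000,
        n_planted_dmps=10,
        delta_beta_range=(0.10, 0.20),
        noise_sd=0.02,
        n_discriminating=300,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(beta, sheet, annot, qc, ref, truth) for a fast 40-sample cohort."""
    return syn.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_adjusted(small_cohort):
    """Filtered + batch-adjusted β with estimated cell proportions."""
    beta, sheet, annot, qc, ref, truth = small_cohort
    filtered, _ = preprocess.filter_probes(beta, annot, qc.detection_p, qc.bead_count)
    adjusted, _ = preprocess.combat_adjust(filtered, sheet)
    cells = cellcomp.estimate_cell_proportions(adjusted, ref)
    return adjusted, sheet, cells, truth


def toy_annotation(positions, chrom="chr1", feature="Body", context="Island"):
    """Minimal annotation frame for hand-built DMR fixtures."""
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.asarray(positions, dtype=np.int64),
            "gene": ["-"] * n,
            "feature": [feature] * n,
            "cpg_context": [context] * n,
            "is_noncg": [False] * n,
            "is_ambiguous": [False] * n,
            "has_snp_at_cg": [False] * n,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id"),
    )
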