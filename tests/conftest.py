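import numpy as np
import pandas as pd
import pytest



@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 12 nuclei of random non-negative log-expression values."""
    vals = np.abs(rng.normal(3.0, 1.0, size=(20, 12)))
    return pd.DataFrame(
        vals,
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"n{i:02d}" for i in range(12)],
    )


@pytest.fixture
def small_metadata(small_matrix, rng):
    n = small_matrix.shape[1]
    return pd.DataFrame(
        {
            "condition": ["HC"] * n,
            "population": ["DG"] * n,
            "fos_protein": ["neg"] * n,
            "arc_protein": ["unknown"] * n,
            "mouse_id": ["m1"] * n,
            "batch_id": ["b0"] * n,
            "total_aligned_reads": rng.integers(200_000, 500_000, n),
            "detected_genes": rng.integers(4_500, 6_000, n),
        },
        index=small_matrix.columns,
    )


def de_table(genes, significant, alpha_value=0.01, null_value=0.9):
    """Construct a minimal differential-expression table for given genes."""
    sig = set(significant)
    p = [alpha_value if g in sig else null_value for g in genes]
    return pd.DataFrame(
        {
            "d": 1.0,
            "mean_a": 2.0,
            "mean_b": 1.0,
            "direction": "up",
            "p_raw": p,
            "p_adj": p,
        },
        index=pd.Index(genes, name="gene"),
    )


def reactivity_truth_labels(truth, matrix):
    """Reactivity class labels (NA/NR/R) from simulation ground truth."""
    nt = truth.nucleus_truth
    lab = pd.Series(np.nan, index=matrix.columns, dtype=object)
    aa = nt["condition"] == "AA"
    lab[nt.index[aa & (nt["activity_state"] == "reactivated")]] = "Reactivated"
    lab[nt.index[aa & (nt["activity_state"] == "early")
                 & (nt["fos_protein"] == "pos") & (nt["arc_protein"] == "pos")]] = "NewlyActivated"
    lab[nt.index[aa & (nt["activity_state"] == "late")]] = "NotReactivated"
    return lab
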