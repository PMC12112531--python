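import numpy as np
import pandas as pd
import pytest

from cortiseq.io import CountMatrix


def make_metadata(sample_ids, treatments=None, timepoints=None):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "treatment": treatments or ["control"] * n,
            "timepoint": timepoints or [5] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with hand-checkable totals."""
    counts = pd.DataFrame(
        [[3, 5], [0, 2], [7, 1]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["s1", "s2"],
    )
    meta = make_metadata(["s1", "s2"], ["control", "cort"], [5, 5])
    return CountMatrix(counts, meta)


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {
            "symbol": ["Aldoa", "Aldoa", "Bfar", "Bfar", "Fos"],
            "biotype": [
                "protein_coding",
                "protein_coding",
                "protein_coding",
                "transcribed_processed_pseudogene",
                "protein_coding",
            ],
            "description": [
                "aldolase A",
                "aldolase A",
                "bifunctional apoptosis regulator",
                "bifunctional apoptosis regulator pseudogene",
                "predicted gene, FBJ osteosarcoma oncogene",
            ],
        },
        index=pd.Index(["E001", "E002", "E003", "E004", "E005"], name="gene_id"),
    )


def two_group_counts(rng, n_genes=200, n_per_group=8, mean_cpm_range=(10, 1000), phi=0.1, lib=1e6):
    """Small NB two-group null matrix used by several DE tests."""
    cpm = 10 ** rng.uniform(np.log10(mean_cpm_range[0]), np.log10(mean_cpm_range[1]), n_genes)
    mu = np.tile(cpm[:, None] * lib / 1e6, (1, 2 * n_per_group))
    y = rng.poisson(rng.gamma(1.0 / phi, phi * mu))
    samples = [f"c{i}" for i in range(n_per_group)] + [f"t{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(y, index=[f"G{i}" for i in range(n_genes)], columns=samples)
    groups = pd.Series(["ctrl"] * n_per_group + ["trt"] * n_per_group, index=samples)
    return counts, groups
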