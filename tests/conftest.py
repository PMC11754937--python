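import numpy as np
import pandas as pd
import pytest

from exuvar.feature_table import FeatureTable
from exuvar.simulate import SimulationConfig, simulate_genotypes


def make_feature_table(areas, accessions, replicates, mode="negative",
                       feature_ids=None, feature_meta=None):
    """Small helper to build a FeatureTable from a dense array."""
    areas = np.asarray(areas, dtype=float)
    n = areas.shape[0]
    if feature_ids is None:
        feature_ids = [f"F{j + 1}" for j in range(areas.shape[1])]
    sample_ids = [f"{a}_r{r}" for a, r in zip(accessions, replicates)]
    peak = pd.DataFrame(areas, index=sample_ids, columns=feature_ids)
    meta = pd.DataFrame(
        {"accession_id": accessions, "replicate": replicates, "mode": mode},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if feature_meta is None:
        feature_meta = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    return FeatureTable(peak_area=peak, sample_meta=meta, feature_meta=feature_meta)


@pytest.fixture(scope="session")
def toy_table():
    """3 accessions x 2 replicates x 4 features with known detections."""
    areas = [
        [10, 0, 2, 1],
        [8, 0, 3, 0],
        [0, 5, 1, 0],
        [0, 4, 2, 0],
        [6, 0, 0, 0],
        [7, 1, 0, 0],
    ]
    return make_feature_table(
        areas,
        ["A", "A", "B", "B", "C", "C"],
        [1, 2, 1, 2, 1, 2],
    )


@pytest.fixture(scope="session")
def structured_genotypes():
    """Default structured population reused by kinship/GWAS tests."""
    cfg = SimulationConfig(n_snps=800, seed=11)
    g, mem = simulate_genotypes(cfg)
    return cfg, g, mem
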