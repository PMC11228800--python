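import numpy as np
import pandas as pd
import pytest

from stniche.io import SpatialDataset, log_normalize
from stniche.niches import NicheLabels
from stniche.synth import ArraySpec, demo_tissue, make_array


def toy_dataset(counts, coords_xy, gene_ids=None, spot_ids=None, normalize=True):
    """Small dense-counts dataset helper for hand-checked examples."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    spot_ids = spot_ids or [f"s{i}" for i in range(n_spots)]
    coords = pd.DataFrame(
        np.asarray(coords_xy, float), index=spot_ids, columns=["x_um", "y_um"]
    )
    ds = SpatialDataset(
        counts=counts, coords=coords, spot_ids=spot_ids, gene_ids=gene_ids
    )
    if normalize:
        log_normalize(ds)
    return ds


def truth_labels(spot_ids, labels):
    """NicheLabels built directly from known per-spot labels."""
    table = pd.DataFrame(
        {
            "spot_id": list(spot_ids),
            "label": list(labels),
            "dominant_type": "truth",
            "dominant_prop": 1.0,
            "rule": "ground truth",
        }
    ).set_index("spot_id")
    return NicheLabels(table)


@pytest.fixture(scope="session")
def default_array():
    return make_array(ArraySpec(), layout="hex")


@pytest.fixture(scope="session")
def demo():
    """One demonstration tissue shared by read-only tests."""
    dataset, truth, markers, pathways = demo_tissue(seed=0)
    log_normalize(dataset)
    return dataset, truth, markers, pathways
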