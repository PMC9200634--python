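"""Shared fixtures: small synthetic atlases, bases and derived objects.

Everything is generated at test time from seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from cforigin import atlas_basis as ab
from cforigin import normalization as nz
from cforigin import synthetic_data as sd


@pytest.fixture(scope="session")
def atlas_small():
    """5 cell types x 200 genes, 10 disjoint markers each at 8x fold."""
    spec = sd.AtlasSpec(
        n_cell_types=5, n_genes=200, cells_per_type=40, markers_per_type=10, seed=1
    )
    return sd.generate_atlas(spec)


@pytest.fixture(scope="session")
def basis_small(atlas_small):
    grouped = ab.coarse_grain(atlas_small, seed=0)
    sub = ab.subsample_cells(grouped, n_max=30, seed=0)
    return ab.build_signature_matrix(sub, barcode_range=(2, 8), seed=0)


@pytest.fixture(scope="session")
def atlas_recovery():
    """10 types x 500 genes, every gene a marker: the recovery benchmark atlas."""
    spec = sd.AtlasSpec(
        n_cell_types=10,
        n_genes=500,
        cells_per_type=50,
        markers_per_type=50,
        seed=11,
    )
    return sd.generate_atlas(spec)


@pytest.fixture(scope="session")
def basis_recovery(atlas_recovery):
    grouped = ab.coarse_grain(atlas_recovery, seed=0)
    sub = ab.subsample_cells(grouped, n_max=30, seed=0)
    return ab.build_signature_matrix(sub, barcode_range=(50, 50), seed=0)


@pytest.fixture(scope="session")
def tissue_table_small(atlas_small):
    return sd.generate_tissue_table(atlas_small, n_extra_tissues=3, seed=0)


@pytest.fixture(scope="session")
def profile_type00(atlas_small, tissue_table_small):
    from cforigin import profiles as pf

    de = pf.single_cell_de(atlas_small, "type_00")
    return pf.derive_profile(de, tissue_table_small, "type_00", "tissue_00")


def make_counts(values: dict[str, list], genes: list[str], plasma=None, bio=None):
    """Small GeneCountMatrix from a dict of sample -> counts."""
    counts = pd.DataFrame(values, index=genes)
    samples = list(values)
    meta = pd.DataFrame(
        {
            "plasma_ml": plasma if plasma is not None else [1.0] * len(samples),
            "batch": "b0",
            "bio_replicate": bio if bio is not None else samples,
        },
        index=samples,
    )
    return nz.GeneCountMatrix(counts=counts, meta=meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
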