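import numpy as np
import pandas as pd
import pytest

import hybridome as h


@pytest.fixture(scope="session")
def design():
    """Standard 3-replicate design for both assays."""
    return h.build_design(3, 3)


@pytest.fixture(scope="session")
def study():
    """A moderate seeded study reused by read-only tests."""
    cfg = h.SimConfig(n_genes=800, n_srna_clusters=800, frac_joint_pairs=0.05, seed=42)
    return h.simulate_study(cfg)


def make_counts(arr, feature_ids=None, library_ids=None):
    arr = np.asarray(arr)
    feature_ids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
    library_ids = library_ids or [f"lib{j}" for j in range(arr.shape[1])]
    return h.CountTable(
        pd.DataFrame(arr, index=pd.Index(feature_ids, name="feature_id"),
                     columns=library_ids)
    )


def make_sheet(library_ids, crosses, assay="endosperm-mRNA"):
    mother = {"PP": "1616A", "PC": "1616A", "CC": "4329B", "CP": "4329B"}
    rows = []
    reps = {}
    for lib, cross in zip(library_ids, crosses):
        reps[cross] = reps.get(cross, 0) + 1
        rows.append((lib, cross, mother[cross], reps[cross], assay))
    return h.SampleSheet(
        pd.DataFrame(
            rows,
            columns=["library_id", "cross", "maternal_plant", "replicate", "assay"],
        )
    )
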