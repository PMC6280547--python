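import numpy as np
import pandas as pd
import pytest

from crossoil import expression_profiles as ep
from crossoil.orthology import OrthoGroup, SpeciesInfo


@pytest.fixture(scope="session")
def species_pair():
    return SpeciesInfo("gma", 2), SpeciesInfo("bna", 4)


@pytest.fixture(scope="session")
def random_ogs():
    """20 OGs with random copy counts over the two species (seeded)."""
    rng = np.random.default_rng(7)
    ogs = []
    for i in range(20):
        ca, cb = int(rng.integers(0, 6)), int(rng.integers(0, 6))
        if ca == 0 and cb == 0:
            ca = 1
        og = OrthoGroup(f"OG{i:03d}")
        og.members["gma"] = [f"gma_{i}_{k}" for k in range(ca)]
        og.members["bna"] = [f"bna_{i}_{k}" for k in range(cb)]
        ogs.append(og)
    return ogs


@pytest.fixture(scope="session")
def profile_catalogue():
    return ep.generate_model_profiles(n_stages=4, c=1, m=20)


@pytest.fixture(scope="session")
def planted_expression(profile_catalogue):
    """A small planted expression matrix plus its true labels."""
    rng = np.random.default_rng(3)
    planted = [p for p in profile_catalogue if len(set(p.shape)) > 1][:5]
    genes, labels, rows = [], {}, []
    for i in range(250):
        p = planted[i % len(planted)]
        g = f"g{i:04d}"
        genes.append(g)
        labels[g] = p.id
        baseline = 2.0 ** rng.normal(3, 1)
        rows.append(baseline * 2.0 ** (np.asarray(p.shape) + rng.normal(0, 0.15, 4)))
    m = pd.DataFrame(rows, index=genes, columns=["t1", "t2", "t3", "t4"])
    return m, labels
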