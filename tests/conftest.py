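import numpy as np
import pandas as pd
import pytest

from modmet.abundance import AbundanceTable
from modmet.catalog import load_packaged_catalog
from modmet.ingest import SampleMetadata


@pytest.fixture(scope="session")
def full_catalog():
    return load_packaged_catalog("full")


@pytest.fixture(scope="session")
def mini_catalog():
    return load_packaged_catalog("mini")


def random_ko_sets(catalog, n_genomes, rng, hit_prob=0.35, decoys=10):
    """Random genome KO sets mixing catalog KOs and decoys (for oracles)."""
    all_kos = sorted(set().union(*(m.kos for m in catalog.modules)))
    decoy_pool = [f"K8{i:04d}" for i in range(200)]
    out = {}
    for i in range(n_genomes):
        take = rng.random(len(all_kos)) < hit_prob
        kos = {k for k, t in zip(all_kos, take) if t}
        kos |= {decoy_pool[j] for j in rng.integers(len(decoy_pool), size=decoys)}
        out[f"G{i:03d}"] = kos
    return out


@pytest.fixture
def toy_abundance():
    """3 genomes x 5 samples over 2 boreholes with hand-set TPM values."""
    tpm = pd.DataFrame(
        {
            "A_S1": [100.0, 50.0, 0.0],
            "A_S2": [0.0, 25.0, 0.0],
            "A_S3": [1000.0, 25.0, 0.0],
            "B_S1": [10.0, 0.0, 5.0],
            "B_S2": [0.0, 0.0, 15.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="genome_id"),
    )
    meta = {
        "A_S1": SampleMetadata("A_S1", "BH-A", 100.0),
        "A_S2": SampleMetadata("A_S2", "BH-A", 100.0),
        "A_S3": SampleMetadata("A_S3", "BH-A", 100.0),
        "B_S1": SampleMetadata("B_S1", "BH-B", 400.0),
        "B_S2": SampleMetadata("B_S2", "BH-B", 400.0),
    }
    return AbundanceTable(tpm=tpm, sample_meta=meta)
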