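import numpy as np
import pandas as pd
import pytest

from sweepscan.datatypes import HaplotypeMatrix, PopulationMap


def build_matrix(haps, positions=None, chrom="1", pops=None, ancestral="ref"):
    """Assemble a HaplotypeMatrix from a raw 0/1 array for tests."""
    haps = np.asarray(haps, dtype=np.uint8)
    n_hap, n_mark = haps.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_mark + 1) * 1000
    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(n_mark)],
        "chrom": chrom, "pos_bp": np.asarray(positions, dtype=np.int64),
        "allele_ref": "A", "allele_alt": "G", "ancestral_state": ancestral})
    n_samp = n_hap // 2
    sample_ids = [f"s{i}" for i in range(n_samp)]
    pop_labels = list(pops) if pops is not None else ["popA"] * n_samp
    m = HaplotypeMatrix(markers, haps, sample_ids, pop_labels)
    m.validate()
    return m


def build_popmap(matrix, group_of=None, cls_of=None):
    pops = sorted(set(matrix.pop_labels))
    group_of = group_of or {p: "NorthAFT" for p in pops}
    cls_of = cls_of or {p: "north_african" for p in pops}
    return PopulationMap(pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "population": matrix.pop_labels,
        "group": [group_of[p] for p in matrix.pop_labels],
        "relatedness_class": [cls_of[p] for p in matrix.pop_labels]}))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_panel(rng):
    """10 haplotypes x 20 markers with irregular spacing, for oracle tests."""
    haps = rng.integers(0, 2, (10, 20)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 200_001), 20, replace=False))
    return build_matrix(haps, positions)


@pytest.fixture(scope="session")
def sweep_dataset():
    """One cached sweep replicate shared by slower integration tests."""
    from sweepscan.simulate import (simulate_wright_fisher,
                                    two_population_study_config)
    return simulate_wright_fisher(two_population_study_config(seed=0))
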