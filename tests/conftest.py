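"""Shared fixtures: tiny constructed panels and one small simulated panel."""

import numpy as np
import pandas as pd
import pytest

from eigensweep.containers import MISSING, GenotypeMatrix, GeneticMap, SampleMetadata
from eigensweep.simulate import SimulationConfig, simulate_panel


def make_geno(calls, marker_type=None, marker_ids=None, sample_ids=None,
              allele_labels=None):
    """Build a GenotypeMatrix from a 2-D list/array of {0, 1, -1} calls."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(m)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    if marker_type is None:
        marker_type = ["PAV"] * m
    return GenotypeMatrix(np.array(marker_ids, dtype=object),
                          np.array(sample_ids, dtype=object),
                          calls,
                          np.array(marker_type, dtype=object),
                          allele_labels)


def make_map(marker_ids, chromosomes, positions):
    return GeneticMap(pd.DataFrame({
        "marker_id": list(marker_ids),
        "chromosome": list(chromosomes),
        "position_cM": list(positions),
    }))


def make_meta(sample_ids, eras, subpops=None):
    t = pd.DataFrame({"sample_id": list(sample_ids), "era": list(eras)})
    if subpops is not None:
        t["subpopulation"] = list(subpops)
    return SampleMetadata(t)


SMALL_CONFIG = SimulationConfig(
    n_markers=800,
    samples_per_subpop=(30, 30, 30, 30, 30),
    n_admixed=20,
    n_sweeps=8,
    sweep_cluster_size=4,
    missing_rate=0.05,
    duplicate_fraction=0.01,
    unmapped_fraction=0.02,
    seed=11,
)


@pytest.fixture(scope="session")
def small_panel():
    """One small Balding–Nichols panel shared by read-only tests."""
    return simulate_panel(SMALL_CONFIG)


@pytest.fixture()
def toy_geno():
    # 4 markers × 5 samples with one missing call
    return make_geno(
        [[0, 0, 1, 1, 1],
         [1, 1, 1, 1, 1],
         [0, 1, 0, 1, MISSING],
         [1, 0, 1, 0, 0]],
        marker_type=["PAV", "PAV", "SNP", "SNP"],
    )
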