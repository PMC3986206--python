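import numpy as np
import pytest

from corecurator.containers import GenotypeMatrix
from corecurator import simulate as sim


@pytest.fixture
def tiny_matrix():
    """4 accessions x 3 markers, fully observed — the worked PIC example."""
    calls = np.array(
        [[0, 0, 0], [1, 1, 1], [0, 1, 0], [0, 0, 1]], dtype=float
    )
    return GenotypeMatrix(["a1", "a2", "a3", "a4"], ["m1", "m2", "m3"], calls)


@pytest.fixture
def small_sim():
    """A small structured simulation shared across tests (seed-pinned)."""
    cfg = sim.SimulationConfig(
        seed=11,
        n_per_subpop=[30, 30, 30, 30, 30],
        n_admixed=50,
        n_markers=600,
        missing_rate=0.02,
        duplicate_sets=[3, 2],
        qtl_spec=[(100, 1.0)],
    )
    gm = sim.generate_map(cfg)
    G, truth = sim.generate_genotypes(cfg, gm)
    return cfg, gm, G, truth
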