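import numpy as np
import pytest

from pcgloop.fragments import map_regions_to_fragments
from pcgloop.loops import bait_class_map, classify_loops, type_baits
from pcgloop.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic dataset (fixed seed), shared across tests."""
    return generate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_classified(default_sim):
    """Bait classes and the classified WT loop table for the default dataset."""
    sim = default_sim
    bait_ids = map_regions_to_fragments(sim.h2aub_peaks, sim.fragments)
    baits = type_baits(bait_ids, sim.fragments, sim.k27_peaks)
    classes = bait_class_map(baits)
    classified, n_dropped = classify_loops(sim.loops_wt, classes)
    return {"baits": baits, "classes": classes, "loops": classified,
            "n_dropped": n_dropped}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
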