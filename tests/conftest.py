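import numpy as np
import pytest

import capmark as cm


@pytest.fixture(scope="session")
def small_sim() -> cm.SimResult:
    """A desk-scale benchmark shared across tests (60 transcripts)."""
    return cm.simulate(cm.SimConfig(n_transcripts=60, seed=1))


@pytest.fixture(scope="session")
def small_run(small_sim):
    return cm.run_pipeline(small_sim.libraries, small_sim.genes, small_sim.sequences)


def make_library(role, contig, strand, depth, starts, library_size=None):
    """Build a one-track Library from plain lists/arrays."""
    track = cm.BaseTrack(contig, strand, np.asarray(depth), np.asarray(starts))
    return cm.Library(role=role, tracks={(contig, strand): track},
                      library_size=library_size)
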