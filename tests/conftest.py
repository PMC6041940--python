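import pytest

from utrapa import PipelineParams, make_genome, plant_duplication


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def world():
    """Small synthetic world used by many pipeline tests."""
    return make_genome(12, seed=1, n_contaminants=3)


@pytest.fixture(scope="session")
def dup_world():
    """World whose first slotted gene hosts a planted 69%-identity duplication."""
    w = make_genome(12, seed=1, n_contaminants=3)
    host = next(g.gene_id for g in w.genes if g.gene_id in w.slots)
    entry = plant_duplication(w, host, identity_target=0.69, intron_offset=10, seed=7)
    return w, entry
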