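import pytest

from cbokit import metamodel as mm
from cbokit import ontology
from cbokit import simulate as sim


@pytest.fixture(scope="session")
def core_hierarchy():
    return ontology.load_core_hierarchy()


@pytest.fixture(scope="session")
def use_case_fragment():
    return mm.load_use_case_fragment()


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One mini tumor-scenario run with every step snapshotted, shared by
    the time-series and acceptance tests: (scenario, directory, events)."""
    out = tmp_path_factory.mktemp("mini_run")
    scen = sim.make_scenario("tumor_angiogenesis_mini")
    link, events = sim.run(scen, out, seed=1, n_steps=60, output_every=1)
    return scen, out, events
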