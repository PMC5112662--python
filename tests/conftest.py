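import numpy as np
import pytest

from pairedrec.simulate import ConversionEvent, PseudogeneEvent, SimConfig, SubgroupConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_scenario() -> SimConfig:
    """A scaled-down cluster (6 + 5 genes) for fast pipeline tests."""
    return SimConfig(
        group1=SubgroupConfig(6, "c1", inhibitory=3, activating=[4]),
        group2=SubgroupConfig(5, "c2", inhibitory=3, activating=[4]),
        recent_duplications=[],
        conversions=[
            ConversionEvent("c103", "c104", "A", "", (25, 103), 5.0),
            ConversionEvent("c103", "c104", "B", "L", (25, 103), 5.0),
            ConversionEvent("c203", "c204", "A", "", (25, 103), 5.0),
            ConversionEvent("c203", "c204", "B", "L", (25, 103), 5.0),
        ],
        s_retained=["c101", "c203"],
        pseudogenes=[PseudogeneEvent("c106", "A", "", "internal_stop")],
        anchoring_overrides={"c101": "GPI"},
    )


@pytest.fixture(scope="session")
def small_family():
    from pairedrec.simulate import simulate_family

    return simulate_family(small_scenario(), seed=3)


@pytest.fixture(scope="session")
def small_family_dir(tmp_path_factory, small_family):
    d = tmp_path_factory.mktemp("family")
    small_family.write(d)
    return d
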