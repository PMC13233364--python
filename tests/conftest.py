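import pytest

from lipomet import PlantConfig, SampleDesign, generate_targeted, generate_untargeted
from lipomet.screening import assign_tiers, run_all_contrasts


@pytest.fixture(scope="session")
def design():
    return SampleDesign.default()


@pytest.fixture(scope="session")
def targeted(design):
    """Default targeted FFA dataset (species x samples) plus truth means."""
    return generate_targeted(seed=1)


@pytest.fixture(scope="session")
def untargeted():
    """Default planted metabolome plus per-feature truth labels."""
    return generate_untargeted(PlantConfig(seed=1))


@pytest.fixture(scope="session")
def contrast_run(untargeted):
    """The six canonical pairwise contrasts and the tier assignment."""
    table, truth = untargeted
    results = run_all_contrasts(table, table.design)
    tiers = assign_tiers(results)
    return results, tiers
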