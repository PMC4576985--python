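import numpy as np
import pytest

from poudimer import synth


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-element peak fixture (4000 peaks, 33 plants)."""
    return synth.generate_peak_fixture(synth.default_plant_spec(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A quick 400-peak fixture with a handful of plants."""
    spec = synth.PlantSpec(
        n_peaks=400,
        peak_len=200,
        plants=(
            synth.PlantElement("MORE-C4", 2),
            synth.PlantElement("MORE-A4", 2),
            synth.PlantElement("PORE", 1),
            synth.PlantElement("SOX_OCT", 1),
        ),
        top_ranks=20,
        seed=11,
    )
    return synth.generate_peak_fixture(spec)
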