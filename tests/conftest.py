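import numpy as np
import pytest

from introgress_stock.ancestry import ReferencePanel
from introgress_stock.simulate import EffectConfig, PanelSpec, simulate_panel


@pytest.fixture(scope="session")
def panel() -> ReferencePanel:
    """Default-layout synthetic panel (48 diagnostic + 33 neutral + 15 mt)."""
    return simulate_panel(PanelSpec(seed=1))


@pytest.fixture(scope="session")
def config() -> EffectConfig:
    return EffectConfig()


@pytest.fixture()
def clean_config() -> EffectConfig:
    """Study conditions without genotyping error or dropout."""
    return EffectConfig(genotyping_error_rate=0.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def toy_panel() -> ReferencePanel:
    """Ten strongly diagnostic loci with hand-set frequencies."""
    rng = np.random.default_rng(7)
    wild = rng.uniform(0.05, 0.3, 10)
    farmed = rng.uniform(0.7, 0.95, 10)
    return ReferencePanel(
        locus_ids=tuple(f"L{i}" for i in range(10)),
        wild_freq=wild,
        farmed_freq=farmed,
        diagnostic=np.ones(10, dtype=bool),
    )
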