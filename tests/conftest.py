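import numpy as np
import pytest

from ugtcap.model import DockingSummary, ModelParams, Panel, VariantRecord
from ugtcap.simulate import PanelSpec, generate_variant_panel


@pytest.fixture
def wild_params() -> ModelParams:
    return ModelParams(sigma=50.0, gamma=8.0, mu=0.4, epsilon=0.0, beta=2.5)


@pytest.fixture
def noise_free_panel(wild_params) -> Panel:
    """20 variants plus wild type, capacities exactly on the sigmoid."""
    spec = PanelSpec(n_variants=20, true_params=wild_params, seed=11)
    panel, _ = generate_variant_panel(spec)
    return panel


def make_summary(variant="V", s_dt=100, s_dh=40, correct=95, ligand="sub"):
    return DockingSummary(
        variant=variant, ligand=ligand, S_DT=s_dt, S_DH=s_dh,
        udpga_correct_count=correct,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
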