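import numpy as np
import pytest

import fibrilkin as fk


@pytest.fixture(scope="session")
def preset_1mg():
    """Rate constants and molar concentration of the 1 mg/ml condition."""
    return fk.RATE_PRESETS[1.0], fk.preset_a0_mM(1.0)


@pytest.fixture(scope="session")
def clean_curve_1mg(preset_1mg):
    """Noise-free OD340 curve from the 1 mg/ml condition, 10-min sampling."""
    rates, a0 = preset_1mg
    obs = fk.ObservationModel(alpha=9.7, baseline=0.02)
    cfg = fk.GeneratorConfig(seed=0, noise_sd=0.0)
    return fk.gen_turbidity(rates, a0, obs, cfg=cfg)


@pytest.fixture(scope="session")
def basis():
    return fk.default_basis()


@pytest.fixture(scope="session")
def traj_1mg(preset_1mg):
    rates, a0 = preset_1mg
    times = np.arange(0.0, 4430.0, 10.0)
    return fk.integrate_assembly(rates, a0, times)
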