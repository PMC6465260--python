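import numpy as np
import pytest

from sidechain_nmr.cest_fit import FitConfig
from sidechain_nmr.spin_models import (
    CestSchedule,
    GlobalExchangeParams,
    SpinExchangeParams,
)


@pytest.fixture
def valine_spin() -> SpinExchangeParams:
    return SpinExchangeParams(
        label="V103CG2",
        shift_ground=1.0,
        shift_excited=-1.2,
        r1=0.20,
        r2_ground=4.0,
        r2_excited=6.0,
        j_cc=35.0,
    )


@pytest.fixture
def exchange() -> GlobalExchangeParams:
    return GlobalExchangeParams(k_ex=128.0, p_e=0.0115)


@pytest.fixture
def schedule() -> CestSchedule:
    return CestSchedule(
        offsets=np.linspace(-600.0, 600.0, 50),
        b1_field=25.0,
        t_sat=0.5,
        spectrometer_freq=150.9,
    )


@pytest.fixture
def fast_fit_config() -> FitConfig:
    """Trimmed multi-start settings for single-spin test fits."""
    return FitConfig(
        init_grid_k_ex=(50.0, 200.0),
        init_grid_p_e=(0.005, 0.03),
        n_refine_starts=2,
        refine_max_nfev=60,
        restart_max_nfev=100,
        n_polish=1,
    )
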