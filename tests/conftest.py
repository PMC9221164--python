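import pytest

from enzytherm import GroundTruth, InactivationFit, decimal_reduction, half_life
from enzytherm import reference as ref


@pytest.fixture
def kd_panel_fits():
    """Per-temperature inactivation fits built from the published kd panel."""
    return [
        InactivationFit(
            T=T,
            kd=kd,
            half_life=half_life(kd),
            D_value=decimal_reduction(kd),
            r_squared=1.0,
            n_points_used=0,
        )
        for T, kd in ref.KD_PANEL.items()
    ]


@pytest.fixture
def noiseless_truth():
    return GroundTruth(noise_cv=0.0, seed=0)
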