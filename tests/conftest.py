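import pytest

from aiirf.calibration import load_default_params


@pytest.fixture(scope="session")
def params():
    """The shipped generator calibration (read once per session)."""
    return load_default_params()


@pytest.fixture()
def linear_params(params):
    """Calibration with every surround weight switched off (linear model)."""
    p = params.copy()
    for bp in p.backgrounds.values():
        bp.w_pre_psp = bp.w_pre_epsc = bp.w_pre_spk = bp.w_post_mv = 0.0
    return p
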