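import numpy as np
import pytest

from cmme_ivp.cmm_io import VelocityMap
from cmme_ivp.synthetic_cmm import InflowParams, generate_inflow_field


@pytest.fixture(scope="session")
def clean_one_beat():
    """Noise-free single-beat inflow map with its timings."""
    params = InflowParams(noise_sd=0.0, n_beats=1)
    vmap, beats = generate_inflow_field(params)
    return params, vmap, beats


@pytest.fixture(scope="session")
def clean_four_beats():
    params = InflowParams(noise_sd=0.0, n_beats=4)
    vmap, beats = generate_inflow_field(params)
    return params, vmap, beats


def make_map(v, ds=0.001, dt=0.005, annulus=None, apex=None, lv_length=None,
             **kw) -> VelocityMap:
    """Convenience constructor for hand-built velocity matrices."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if apex is None:
        apex = n - 1
    if annulus is None:
        annulus = 0
    if lv_length is None:
        lv_length = (apex - annulus) * ds
    return VelocityMap(v=v, ds=ds, dt=dt, s0_annulus_index=annulus,
                       apex_index=apex, lv_length=lv_length, **kw)
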