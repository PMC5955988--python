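import numpy as np
import pytest
from hypothesis import settings

import onhlab as ol
from onhlab.synthetic import PhantomParams, generate_oct_phantom, pit_depth_for_target

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def small_phantom(**overrides) -> PhantomParams:
    """Desk-scale phantom (160 x 160 x 384) for unit tests; same spacings."""
    kw = dict(n_bscans=160, n_ascans=160, n_depth=384, seed=7)
    kw.update(overrides)
    return PhantomParams(**kw)


def detrend(s: np.ndarray) -> np.ndarray:
    idx = np.arange(len(s))
    return s - np.polyval(np.polyfit(idx, s, 1), idx)


@pytest.fixture(scope="session")
def default_chain():
    """Segmentation products on a default-speckle phantom.

    Generated without motion so the volume satisfies the segmenter's
    registered-input precondition; registration accuracy has its own
    fixtures, and the full jittered chain is exercised end to end at study
    scale by the depression-recovery test.
    """
    params = small_phantom(
        seed=11, pit_depth_um=pit_depth_for_target(89.3), jitter_sigma_px=0.0
    )
    vol, gt = generate_oct_phantom(params)
    ilm, rpe = ol.segment_surfaces(vol)
    elev = ol.surface_to_elevation(ilm, vol)
    center = ol.detect_onh_center(elev)
    return {
        "params": params,
        "vol": vol,
        "gt": gt,
        "ilm": ilm,
        "rpe": rpe,
        "elev": elev,
        "center": center,
    }


@pytest.fixture(scope="session")
def noiseless_jitter_chain():
    """Noiseless flat phantom with programmed random-walk jitter."""
    params = small_phantom(
        seed=3, pit_depth_um=0.0, jitter_sigma_px=5.0, speckle_contrast=0.0, additive_noise=0.0
    )
    vol, gt = generate_oct_phantom(params)
    reg, rr = ol.register_bscans(vol)
    return {"params": params, "vol": vol, "gt": gt, "reg": reg, "rr": rr}


@pytest.fixture(scope="session")
def flat_noiseless_volume():
    """Flat surface at exactly 100 px depth, zero noise, zero jitter."""
    params = small_phantom(
        seed=0,
        pit_depth_um=0.0,
        jitter_sigma_px=0.0,
        speckle_contrast=0.0,
        additive_noise=0.0,
        surface_reference_px=100.0,
    )
    vol, gt = generate_oct_phantom(params)
    return {"params": params, "vol": vol, "gt": gt}
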