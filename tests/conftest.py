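import numpy as np
import pytest

from erpmarker.containers import WINDOWS, EpochSet
from erpmarker.montage import build_montage, scalp_regions


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def regions(montage):
    return scalp_regions(montage)


def make_epochs(data, task="VGNG", condition="Go", lock="stimulus",
                correct=None, rt=None, subject_id="s1"):
    """EpochSet around a raw (trials, channels, times) array."""
    n = data.shape[0]
    return EpochSet(
        subject_id=subject_id, task=task, condition=condition, lock=lock,
        data=data,
        correct=np.ones(n, dtype=bool) if correct is None else correct,
        rt=np.full(n, np.nan) if rt is None else rt,
    )


def gabor_erp_data(montage, peak_channel="Cz", peak_time_ms=200.0,
                   amplitude=5.0, temporal_sd_ms=40.0, spatial_sd=0.5,
                   task="VGNG", lock="stimulus", carrier_hz=0.0):
    """(channels, times) array holding one spatiotemporal bump."""
    win = WINDOWS[(task, lock)]
    t = win.times()
    idx = montage.index(peak_channel)
    center = montage.positions()[idx]
    d2 = ((montage.positions() - center) ** 2).sum(axis=1)
    spatial = np.exp(-0.5 * d2 / spatial_sd ** 2)
    envelope = np.exp(-0.5 * ((t - peak_time_ms) / temporal_sd_ms) ** 2)
    if carrier_hz:
        envelope = envelope * np.cos(2e-3 * np.pi * carrier_hz
                                     * (t - peak_time_ms))
    return amplitude * np.outer(spatial, envelope)
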