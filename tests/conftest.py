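"""Shared fixtures: synthetic stacks are expensive, so they are session-scoped."""

import numpy as np
import pytest

from meioquant import imagequant as iq
from meioquant import synthetic as syn


@pytest.fixture(scope="session")
def small_stack():
    """An 8-nucleus stack with 6 foci per nucleus at SNR 10."""
    volume, truth = syn.simulate_germline_stack(
        n_nuclei=8, axis_ratio=0.7, foci_per_nucleus=6, snr=10.0, seed=2
    )
    return volume, truth


@pytest.fixture(scope="session")
def small_stack_backgrounds(small_stack):
    volume, _ = small_stack
    return {
        name: iq.background_annulus(ch, volume.labels)
        for name, ch in volume.channels.items()
    }


@pytest.fixture(scope="session")
def small_stack_records(small_stack, small_stack_backgrounds):
    volume, _ = small_stack
    return iq.nucleus_metrics(
        volume, small_stack_backgrounds, axis_channel="axis", ratio_channel="sc"
    )


@pytest.fixture(scope="session")
def noiseless_stack():
    """A 6-nucleus noise-free stack (snr=inf) for exact recoveries."""
    volume, truth = syn.simulate_germline_stack(
        n_nuclei=6, axis_ratio=0.7, foci_per_nucleus=2, snr=np.inf, seed=11
    )
    return volume, truth
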