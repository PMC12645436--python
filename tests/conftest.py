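"""Shared fixtures: small synthetic runs and peak builders."""

import numpy as np
import pytest

from flowspps.peak_analysis import DeprotectionPeak
from flowspps.synthetic_data import SimulationConfig, simulate_deprotection_trace


LABELS_16 = tuple(f"{aa}{90 - i}" for i, aa in enumerate("GRLWVAESTKDFQYHL"))


@pytest.fixture(scope="session")
def labels16():
    """16 residue labels in synthesis (C→N) order, parent numbering 90→75."""
    return LABELS_16


@pytest.fixture(scope="session")
def clean_run(labels16):
    """Noiseless 16-residue Gaussian run without aggregation."""
    config = SimulationConfig(
        sequence_labels=labels16,
        peak_model="gaussian",
        noise_sd_au=0.0,
        seed=0,
    )
    return simulate_deprotection_trace(config)


@pytest.fixture(scope="session")
def aggregating_run(labels16):
    """Noiseless EMG run aggregating from synthesis index 7."""
    config = SimulationConfig(
        sequence_labels=labels16,
        onset_index=7,
        broadening_rate=0.15,
        yield_per_residue=0.97,
        noise_sd_au=0.0,
        seed=0,
    )
    return simulate_deprotection_trace(config)


def make_peak(label="X1", idx=0, h=1.0, w=4.0, area=None, flags=frozenset(),
              apex=10.0):
    """DeprotectionPeak with given metrics (area defaults to h·w)."""
    return DeprotectionPeak(
        residue_label=label,
        cycle_index=idx,
        apex_time_s=apex,
        height_au=h,
        fwhm_s=w,
        area_au_s=area if area is not None else h * w,
        flags=flags,
    )


def gaussian_window(sigma=2.0, height=1.0, dt=0.1, span=90.0, center=None):
    """(t, y) samples of an isolated Gaussian peak in a window."""
    t = np.arange(0.0, span, dt)
    mu = span / 2.0 if center is None else center
    y = height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return t, y
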