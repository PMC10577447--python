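"""Shared fixtures: small layouts, drives, and cached simulations.

Simulation-backed fixtures are session-scoped so expensive synthetic
datasets are generated once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from rfttag.stimulus import Condition, make_drive_waveform
from rfttag.synthmeg import GainModel, default_layout, simulate_conditions


@pytest.fixture(scope="session")
def layout():
    """12 posterior + 12 other triplet positions (72 channels)."""
    return default_layout(12, 12, seed=0)


@pytest.fixture(scope="session")
def small_layout():
    """8 posterior + 4 other positions, gradiometers only (24 channels)."""
    return default_layout(8, 4, seed=0, include_mags=False)


@pytest.fixture(scope="session")
def drive60():
    """Reference 60 Hz drive at the MEG sampling rate."""
    return make_drive_waveform(60.0, 1000.0)


def noiseless_gain(scale: float = 0.3, lag_s: float = 0.01) -> GainModel:
    """A gain model whose sensors carry an exact scaled, delayed drive copy.

    All noise, jitter and topography terms are switched off and the flat
    sensor profile makes every channel ``scale`` times the drive modulation.
    The lower-central reference position has unit position gain.
    """
    return GainModel(
        amp0=scale, participant_sigma=0.0, response_phase_lag_s=lag_s,
        phase_jitter_sd=0.0, harmonic2_gain_mag=0.0, harmonic2_gain_grad=0.0,
        mag_snr_factor=1.0, contralateral_bias=0.0, profile_width=1e6,
        one_over_f_amp=0.0, alpha_amp=0.0, white_sd=0.0,
        photodiode_noise_sd=0.0,
    )


NOISELESS_COND = Condition(freq_hz=60.0, size_deg=6.0, position_deg=(0.0, -6.0))


@pytest.fixture(scope="session")
def noiseless_epochs(small_layout):
    """20 identical noiseless trials: sensors = 0.3 x drive, 10 ms delay."""
    return simulate_conditions([NOISELESS_COND], 20, noiseless_gain(),
                               small_layout, n_participants=1, seed=0)[0]


@pytest.fixture(scope="session")
def lownoise_epochs(small_layout):
    """Near-noiseless tagging with a faint noise floor on sensors and diode.

    The baseline interval then carries independent noise (coherence near
    the 1/N floor) while the stimulation interval is signal-dominated.
    """
    import dataclasses

    gm = dataclasses.replace(noiseless_gain(), white_sd=0.01,
                             photodiode_noise_sd=0.01)
    return simulate_conditions([NOISELESS_COND], 20, gm, small_layout,
                               n_participants=1, seed=3)[0]


@pytest.fixture(scope="session")
def tagged_epochs(layout):
    """One participant, 12 default-gain 60 Hz trials (with noise)."""
    return simulate_conditions([Condition(freq_hz=60.0)], 12, GainModel(),
                               layout, n_participants=1, seed=42)[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
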