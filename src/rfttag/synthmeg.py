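"""Synthetic multi-sensor MEG with a known, parameterized tagging response.

No public dataset accompanies the experiment, so every downstream stage is
exercised against simulated recordings whose ground truth is fully known.
The simulator emulates the features that matter for the analysis:

* a sensor array of co-located planar-gradiometer pairs plus magnetometers
  laid out on a 2D head disc, with a posterior (occipital) arc where the
  visual response concentrates;
* a steady-state response phase-locked to the photodiode drive whose
  amplitude declines with drive frequency, grows with patch size, and
  varies over the 3 x 5 position grid (lower visual field and central
  columns strongest, contralateral hemisphere favoured);
* background noise with a 1/f spectrum, a 10 Hz alpha peak, and a white
  floor; multiplicative between-participant gain variability.

It does not attempt forward modelling with realistic head geometry, nor
ocular/cardiac artefacts (preprocessing is out of scope of the pipeline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stimulus import (
    Condition,
    DriveWaveform,
    SessionType,
    TrialSchedule,
    make_drive_waveform,
    schedule_session,
)

__all__ = [
    "SensorLayout",
    "GainModel",
    "EpochSet",
    "default_layout",
    "simulate_epoch",
    "simulate_epochs",
    "simulate_conditions",
    "simulate_study",
]

#: Epoch geometry: 1.2 s fixation baseline, 0.2 s ramp-up, 1 s full
#: stimulation, 0.2 s ramp-down, 0.2 s post-stimulation fixation -> 2.8 s,
#: with t = 0 at full-stimulation onset.
EPOCH_START_S = -1.4
EPOCH_STOP_S = 1.4
DEFAULT_FS_HZ = 1000.0

PHOTODIODE_ID = "diode"


@dataclass(frozen=True)
class SensorLayout:
    """A simplified MEG sensor array on the unit head disc.

    ``channels`` has one row per physical channel with columns id, x, y,
    type ('grad' or 'mag'), pair_id (position index; the two gradiometers
    of a pair share it), hemisphere ('L'/'R'/'M'), posterior (bool).
    ``positions`` holds the pair-combined 2D coordinates and
    ``adjacency`` the symmetric position-level neighbourhood matrix used by
    the cluster permutation test.
    """

    channels: pd.DataFrame = field(repr=False)
    positions: np.ndarray = field(repr=False)
    adjacency: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def channel_ids(self) -> list[str]:
        return list(self.channels["id"])

    def channel_indices(self, sensor_type: str | None = None) -> np.ndarray:
        ch = self.channels
        mask = np.ones(len(ch), dtype=bool)
        if sensor_type is not None:
            mask &= (ch["type"] == sensor_type).to_numpy()
        return np.flatnonzero(mask)

    def posterior_positions(self) -> np.ndarray:
        """Indices of posterior pair-positions (the default sensor set)."""
        ch = self.channels.drop_duplicates("pair_id")
        return ch.loc[ch["posterior"], "pair_id"].to_numpy()

    def position_hemisphere(self) -> np.ndarray:
        hemi = np.where(self.positions[:, 0] < -1e-9, "L",
                        np.where(self.positions[:, 0] > 1e-9, "R", "M"))
        return hemi

    def to_csv(self, path: str | Path) -> None:
        self.channels.to_csv(path, index=False)


def default_layout(n_posterior: int = 12, n_other: int = 12, seed: int = 0,
                   include_mags: bool = True) -> SensorLayout:
    """Construct a sensor layout with ``n_posterior + n_other`` positions.

    Each position hosts a co-located orthogonal gradiometer pair and,
    unless ``include_mags`` is False, a magnetometer (Neuromag-style
    triplet).  Posterior positions sit on two
    occipital arcs at the bottom of the head disc; the rest tile the
    remaining scalp on a sunflower spiral.  Adjacency connects positions
    closer than a threshold chosen just above the largest nearest-neighbour
    distance, so every position has at least one neighbour.
    """
    if n_posterior < 4:
        raise ValueError("need at least 4 posterior positions")
    if n_posterior + n_other < 2:
        raise ValueError("need at least 2 sensor positions")
    rng = np.random.default_rng(seed)

    pos = []
    # posterior: arcs spanning the occipital quadrant (y < 0)
    n_arc1 = (n_posterior + 1) // 2
    n_arc2 = n_posterior - n_arc1
    for radius, count in ((0.88, n_arc1), (0.62, n_arc2)):
        if count == 0:
            continue
        ang = np.linspace(-5 * np.pi / 6, -np.pi / 6, count)
        pos.extend(zip(radius * np.cos(ang), radius * np.sin(ang)))
    # remaining scalp: sunflower spiral over the upper part of the disc
    golden = np.pi * (3 - np.sqrt(5))
    k = np.arange(1, 4 * max(n_other, 1) + 1)
    rr = 0.92 * np.sqrt(k / k[-1])
    th = k * golden
    cand = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    cand = cand[cand[:, 1] > -0.25][:n_other]
    pos.extend(map(tuple, cand))
    positions = np.asarray(pos, dtype=float)
    positions = positions + rng.normal(scale=0.005, size=positions.shape)

    # adjacency from a distance threshold guaranteeing >= 1 neighbour each
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = 1.05 * d.min(axis=1).max()
    adjacency = d <= max(thresh, 0.35)
    np.fill_diagonal(adjacency, False)

    triplet = (("g1", "grad"), ("g2", "grad"), ("m", "mag"))
    if not include_mags:
        triplet = triplet[:2]
    rows = []
    for p, (x, y) in enumerate(positions):
        hemi = "L" if x < -1e-9 else ("R" if x > 1e-9 else "M")
        posterior = bool(y < -0.25)
        for suffix, typ in triplet:
            rows.append(dict(id=f"P{p:02d}{suffix}", x=x, y=y, type=typ,
                             pair_id=p, hemisphere=hemi, posterior=posterior))
    channels = pd.DataFrame(rows)
    if not channels["posterior"].any():
        raise ValueError("layout has no posterior sensors")
    return SensorLayout(channels=channels, positions=positions,
                        adjacency=adjacency, seed=seed)


@dataclass(frozen=True)
class GainModel:
    """Ground-truth response and noise parameters of the simulator.

    The tagging response in a sensor channel is

    ``participant_gain * amp0 * freq_gain(f) * size_gain(s) *
    position_gain(x, y) * sensor_profile * envelope(t - lag) *
    sin(2*pi*f*(t - lag) + jitter)``

    plus an optional second harmonic, on top of 1/f background noise, an
    alpha (10 Hz) oscillation and a white floor.  Gains are dimensionless
    multipliers; ``amp0`` sets the response amplitude (a.u.) of the best
    posterior sensor at the 60 Hz / 6-degree / central reference condition.
    """

    amp0: float = 0.15
    # frequency tuning: linear decline, 1 at freq_ref_hz, 0 at/above cutoff
    freq_ref_hz: float = 60.0
    freq_cutoff_hz: float = 88.0
    # size tuning: linear growth through the origin, 1 at size_ref_deg
    size_ref_deg: float = 6.0
    # position tuning: separable vertical x horizontal multipliers
    row_gain_lower: float = 1.0
    row_gain_middle: float = 0.78
    row_gain_upper: float = 0.52
    col_gain_center: float = 1.0
    col_gain_near: float = 0.74   # |x| = 6 deg
    col_gain_far: float = 0.48    # |x| = 12 deg
    # per-participant multiplicative gain ~ lognormal(0, participant_sigma)
    participant_sigma: float = 0.35
    # response dynamics
    response_phase_lag_s: float = 0.05
    phase_jitter_sd: float = 0.15
    harmonic2_gain_grad: float = 0.0
    harmonic2_gain_mag: float = 0.12
    mag_snr_factor: float = 1.3
    contralateral_bias: float = 0.35
    # sensor response topography: Gaussian falloff from the occipital pole
    profile_center: tuple[float, float] = (0.0, -0.85)
    profile_width: float = 0.4
    # noise: amplitude-spectrum weights for the 1/f and alpha components,
    # plus a white time-domain floor (all a.u.)
    one_over_f_exponent: float = 1.0
    one_over_f_amp: float = 12.0
    alpha_freq_hz: float = 10.0
    alpha_amp: float = 150.0
    alpha_width_hz: float = 1.5
    white_sd: float = 1.2
    photodiode_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        gains = (self.amp0, self.row_gain_lower, self.row_gain_middle,
                 self.row_gain_upper, self.col_gain_center, self.col_gain_near,
                 self.col_gain_far)
        if any(g < 0 for g in gains):
            raise ValueError("gains must be non-negative")
        if not (self.row_gain_lower >= self.row_gain_middle >= self.row_gain_upper):
            raise ValueError("row gains must be ordered lower >= middle >= upper")

    def freq_gain(self, freq_hz: float) -> float:
        """Linear decline from 1 at the reference frequency to 0 at cutoff."""
        span = self.freq_cutoff_hz - self.freq_ref_hz
        return float(np.clip((self.freq_cutoff_hz - freq_hz) / span, 0.0, None))

    def size_gain(self, size_deg: float) -> float:
        if size_deg < 0:
            raise ValueError("patch size must be non-negative")
        return float(size_deg / self.size_ref_deg)

    def position_gain(self, position_deg: tuple[float, float]) -> float:
        x, y = position_deg
        if y < -1e-9:
            row = self.row_gain_lower
        elif y > 1e-9:
            row = self.row_gain_upper
        else:
            row = self.row_gain_middle
        ax = abs(x)
        if ax < 3.0:
            col = self.col_gain_center
        elif ax < 9.0:
            col = self.col_gain_near
        else:
            col = self.col_gain_far
        return float(row * col)

    def participant_gain(self, participant_index: int, seed: int = 0) -> float:
        """Lognormal per-participant gain, fixed by (seed, participant)."""
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919, participant_index]))
        return float(np.exp(rng.normal(0.0, self.participant_sigma)))

    def sensor_profile(self, layout: SensorLayout, condition: Condition) -> np.ndarray:
        """Per-channel spatial weights of the tagging response.

        Gaussian falloff from the occipital pole, a contralateral boost for
        lateral patch positions, and the magnetometer SNR multiplier.
        """
        ch = layout.channels
        dx = ch["x"].to_numpy() - self.profile_center[0]
        dy = ch["y"].to_numpy() - self.profile_center[1]
        w = np.exp(-(dx**2 + dy**2) / (2 * self.profile_width**2))
        x_stim = condition.position_deg[0]
        if abs(x_stim) > 1e-9:
            contra = "R" if x_stim < 0 else "L"
            hemi = ch["hemisphere"].to_numpy()
            w = w * np.where(hemi == contra, 1 + self.contralateral_bias,
                             np.where(hemi == "M", 1.0, 1 - self.contralateral_bias))
        w = w * np.where(ch["type"].to_numpy() == "mag", self.mag_snr_factor, 1.0)
        return w

    def response_amplitude(self, condition: Condition) -> float:
        return (self.amp0 * self.freq_gain(condition.freq_hz)
                * self.size_gain(condition.size_deg)
                * self.position_gain(condition.position_deg))

    def null(self) -> "GainModel":
        """A copy with zero tagging response (noise-only channels)."""
        return replace(self, amp0=0.0)


@dataclass
class EpochSet:
    """Trials x channels x time container with condition labels.

    The last channel is always the photodiode.  The time axis spans
    -1.4 .. +1.4 s with t = 0 at full-stimulation onset.
    """

    data: np.ndarray = field(repr=False)
    sample_rate_hz: float
    times_s: np.ndarray = field(repr=False)
    channel_ids: list[str]
    photodiode_channel_id: str
    trial_info: pd.DataFrame = field(repr=False)
    participant_id: str = "sub-00"
    layout: SensorLayout | None = None

    def __post_init__(self) -> None:
        if self.channel_ids.count(self.photodiode_channel_id) != 1:
            raise ValueError("exactly one photodiode channel required")
        if self.data.shape[1] != len(self.channel_ids):
            raise ValueError("channel axis does not match channel_ids")
        if len(self.trial_info) != self.data.shape[0]:
            raise ValueError("trial_info does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def photodiode_index(self) -> int:
        return self.channel_ids.index(self.photodiode_channel_id)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            sample_rate_hz=self.sample_rate_hz,
            times_s=self.times_s,
            channel_ids=self.channel_ids,
            photodiode_channel_id=self.photodiode_channel_id,
            trial_info=self.trial_info.loc[mask].reset_index(drop=True),
            participant_id=self.participant_id,
            layout=self.layout,
        )

    def tagging_trials(self) -> "EpochSet":
        """Drop response (task) trials; they are not analysed."""
        return self.select_trials((self.trial_info["kind"] == "rft").to_numpy())

    def save(self, path: str | Path) -> None:
        """Persist as a .npz array container plus a JSON/CSV sidecar pair."""
        path = Path(path)
        np.savez_compressed(path, data=self.data, times_s=self.times_s)
        meta = {
            "sample_rate_hz": self.sample_rate_hz,
            "channel_ids": self.channel_ids,
            "photodiode_channel_id": self.photodiode_channel_id,
            "participant_id": self.participant_id,
        }
        base = path.with_suffix("")
        Path(f"{base}.json").write_text(json.dumps(meta, indent=2))
        self.trial_info.to_csv(f"{base}.trials.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, layout: SensorLayout | None = None) -> "EpochSet":
        path = Path(path)
        arrs = np.load(path)
        base = path.with_suffix("")
        meta = json.loads(Path(f"{base}.json").read_text())
        trial_info = pd.read_csv(f"{base}.trials.tsv", sep="\t")
        return cls(data=arrs["data"], sample_rate_hz=meta["sample_rate_hz"],
                   times_s=arrs["times_s"], channel_ids=meta["channel_ids"],
                   photodiode_channel_id=meta["photodiode_channel_id"],
                   trial_info=trial_info, participant_id=meta["participant_id"],
                   layout=layout)


def _colored_noise(shape: tuple[int, ...], fs: float, gm: GainModel,
                   rng: np.random.Generator, dtype=np.float64) -> np.ndarray:
    """1/f + alpha-bump + white noise along the last axis.

    Built in the frequency domain: independent complex-Gaussian bins shaped
    by an amplitude profile (1/f trend, Gaussian alpha bump, flat white
    floor scaled so its time-domain SD equals ``white_sd``).
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = gm.one_over_f_amp * freqs[nz] ** (-gm.one_over_f_exponent / 2)
    amp += gm.alpha_amp * np.exp(-((freqs - gm.alpha_freq_hz) ** 2)
                                 / (2 * gm.alpha_width_hz**2))
    amp += gm.white_sd * n / np.sqrt(2 * fs)
    spec_shape = shape[:-1] + (freqs.size,)
    spec = (rng.standard_normal(spec_shape, dtype=dtype)
            + 1j * rng.standard_normal(spec_shape, dtype=dtype))
    spec *= amp.astype(dtype)
    return np.fft.irfft(spec, n=n, axis=-1) * dtype(np.sqrt(fs / n))


def _epoch_times(fs: float) -> np.ndarray:
    n = int(round((EPOCH_STOP_S - EPOCH_START_S) * fs))
    return EPOCH_START_S + np.arange(n) / fs


def _embedded_envelope(drive: DriveWaveform, times: np.ndarray, fs: float) -> np.ndarray:
    """The drive envelope on the epoch time axis (zero outside the train)."""
    if abs(drive.sample_rate_hz - fs) > 1e-9:
        t_native = drive.times_s
        return np.interp(times, t_native, drive.envelope, left=0.0, right=0.0)
    env = np.zeros_like(times)
    start = int(round((-drive.ramp_duration_s - EPOCH_START_S) * fs))
    env[start:start + drive.envelope.size] = drive.envelope
    return env


def simulate_epoch(
    drive: DriveWaveform,
    condition: Condition,
    gain_model: GainModel,
    layout: SensorLayout,
    seed: int | np.random.Generator = 0,
    participant_gain: float = 1.0,
) -> np.ndarray:
    """Simulate one trial: (n_channels + 1) x n_times, photodiode last."""
    out = simulate_epochs(drive, [condition], gain_model, layout, seed=seed,
                          participant_gain=participant_gain)
    return out[0]


def simulate_epochs(
    drive: DriveWaveform,
    conditions: Sequence[Condition],
    gain_model: GainModel,
    layout: SensorLayout,
    seed: int | np.random.Generator = 0,
    participant_gain: float = 1.0,
    dtype=np.float64,
) -> np.ndarray:
    """Simulate a batch of trials sharing one drive envelope.

    Each trial uses the drive frequency of its own condition (the envelope
    and timing come from ``drive``).  Returns trials x channels x time with
    the photodiode as the last channel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = DEFAULT_FS_HZ
    times = _epoch_times(fs)
    env = _embedded_envelope(drive, times, fs)
    n_ch = len(layout.channel_ids)
    n_tr = len(conditions)

    data = np.empty((n_tr, n_ch + 1, times.size), dtype=dtype)
    data[:, :n_ch, :] = _colored_noise((n_tr, n_ch, times.size), fs, gain_model,
                                       rng, dtype=dtype)

    is_mag = (layout.channels["type"] == "mag").to_numpy()
    lag = gain_model.response_phase_lag_s
    env_lag = np.interp(times - lag, times, env, left=0.0, right=0.0)

    for k, cond in enumerate(conditions):
        f = cond.freq_hz
        amp = participant_gain * gain_model.response_amplitude(cond)
        jitter = rng.normal(0.0, gain_model.phase_jitter_sd) if gain_model.phase_jitter_sd > 0 else 0.0
        profile = gain_model.sensor_profile(layout, cond)
        phase = 2 * np.pi * f * (times - lag) + drive.phase0 + jitter
        carrier = env_lag * np.sin(phase)
        signal = amp * profile[:, None] * carrier[None, :]
        h2 = np.where(is_mag, gain_model.harmonic2_gain_mag, gain_model.harmonic2_gain_grad)
        if np.any(h2 > 0):
            carrier2 = env_lag * np.sin(2 * phase)
            signal = signal + amp * (profile * h2)[:, None] * carrier2[None, :]
        data[k, :n_ch, :] += signal

        # photodiode: the luminance drive itself (mid-grey outside the train)
        diode = drive.baseline_luminance + 0.5 * drive.modulation_depth * env * np.sin(
            2 * np.pi * f * times + drive.phase0)
        if gain_model.photodiode_noise_sd > 0:
            diode = diode + gain_model.photodiode_noise_sd * rng.standard_normal(times.size)
        data[k, n_ch, :] = diode
    return data


def _epochs_from_schedule(
    schedule: TrialSchedule,
    gain_model: GainModel,
    layout: SensorLayout,
    participant_id: str,
    participant_gain: float,
    rng: np.random.Generator,
    n_trials_override: int | None,
    drive_kwargs: dict,
) -> EpochSet:
    trials = schedule.trials
    if n_trials_override is not None:
        # keep the first n tagging trials per condition (plus no task trials)
        rft = trials[trials["kind"] == "rft"]
        keep = rft.groupby("condition_id", sort=False).head(n_trials_override)
        trials = keep.sort_index().reset_index(drop=True)
    else:
        trials = trials.reset_index(drop=True)

    fs = DEFAULT_FS_HZ
    conditions = [
        Condition(freq_hz=row.freq_hz, size_deg=row.size_deg,
                  position_deg=(row.pos_x_deg, row.pos_y_deg))
        for row in trials.itertuples()
    ]
    drive = make_drive_waveform(freq_hz=60.0, sample_rate_hz=fs, **drive_kwargs)
    data = simulate_epochs(drive, conditions, gain_model, layout, seed=rng,
                           participant_gain=participant_gain)
    return EpochSet(
        data=data,
        sample_rate_hz=fs,
        times_s=_epoch_times(fs),
        channel_ids=layout.channel_ids + [PHOTODIODE_ID],
        photodiode_channel_id=PHOTODIODE_ID,
        trial_info=trials.copy(),
        participant_id=participant_id,
        layout=layout,
    )


def simulate_conditions(
    conditions: Sequence[Condition],
    n_trials: int,
    gain_model: GainModel | None = None,
    layout: SensorLayout | None = None,
    n_participants: int = 1,
    seed: int = 0,
    dtype=np.float64,
) -> list[EpochSet]:
    """Simulate ``n_trials`` epochs of each condition for each participant.

    A lightweight alternative to :func:`simulate_study` for custom condition
    sets (mini sweeps, single-condition null data); trial order is the
    condition list repeated, not a schedule.
    """
    gain_model = gain_model or GainModel()
    layout = layout or default_layout()
    drive = make_drive_waveform(freq_hz=60.0, sample_rate_hz=DEFAULT_FS_HZ)
    conditions = list(conditions)
    ss = np.random.SeedSequence(seed)
    out = []
    for p, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        conds = [c for c in conditions for _ in range(n_trials)]
        data = simulate_epochs(drive, conds, gain_model, layout, seed=rng,
                               participant_gain=gain_model.participant_gain(p, seed),
                               dtype=dtype)
        info = pd.DataFrame([
            dict(block=0, kind="rft",
                 condition_id=f"c{conditions.index(c):02d}",
                 freq_hz=c.freq_hz, size_deg=c.size_deg,
                 pos_x_deg=c.position_deg[0], pos_y_deg=c.position_deg[1])
            for c in conds])
        out.append(EpochSet(
            data=data, sample_rate_hz=DEFAULT_FS_HZ,
            times_s=_epoch_times(DEFAULT_FS_HZ),
            channel_ids=layout.channel_ids + [PHOTODIODE_ID],
            photodiode_channel_id=PHOTODIODE_ID, trial_info=info,
            participant_id=f"sub-{p:02d}", layout=layout))
    return out


def simulate_study(
    session_type: SessionType | str,
    gain_model: GainModel | None = None,
    layout: SensorLayout | None = None,
    n_participants: int = 11,
    n_trials_override: int | None = None,
    seed: int = 0,
    drive_kwargs: dict | None = None,
) -> list[EpochSet]:
    """Simulate one session for every participant.

    Each participant gets an independently seeded schedule and noise stream
    plus a lognormal multiplicative gain.  ``n_trials_override`` keeps only
    the first N tagging trials per condition (and drops task trials) for
    fast, scaled-down runs; identical seeds give bit-identical data.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    gain_model = gain_model or GainModel()
    layout = layout or default_layout()
    drive_kwargs = drive_kwargs or {}

    seedseq = np.random.SeedSequence(seed)
    children = seedseq.spawn(n_participants)
    out = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        sched = schedule_session(session_type, seed=int(child.generate_state(1)[0] % (2**31)))
        pg = gain_model.participant_gain(p, seed=seed)
        out.append(_epochs_from_schedule(
            sched, gain_model, layout, participant_id=f"sub-{p:02d}",
            participant_gain=pg, rng=rng, n_trials_override=n_trials_override,
            drive_kwargs=drive_kwargs))
    return out
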