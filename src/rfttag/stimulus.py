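"""Rapid-frequency-tagging (RFT) stimulus construction.

RFT drives a circular screen patch with a sinusoidal luminance modulation
above the flicker-fusion threshold (>60 Hz).  The drive is invisible to the
observer but phase-locks a steady-state response in visual cortex that can
be read out with MEG.  This module builds the three experiment-defining
objects:

* the temporal drive waveform (sinusoid under half-Hanning on/off ramps),
* the radial spatial taper that hides the patch edge, and
* seeded trial schedules for the three session types (frequency sweep,
  patch-size sweep, and a 3 x 5 grid of patch positions).

Time convention: t = 0 is the onset of *full* stimulation, i.e. the end of
the ramp-up.  A 1.4 s train with 0.2 s ramps therefore spans -0.2 .. +1.2 s
and the plateau spans 0 .. 1 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DriveWaveform",
    "TaperMask",
    "TrialSchedule",
    "Condition",
    "SessionType",
    "make_drive_waveform",
    "make_spatial_taper",
    "schedule_session",
]


class SessionType(str, Enum):
    """The three experimental sessions."""

    FREQ = "FREQ"
    SIZE = "SIZE"
    POSITION = "POSITION"


#: Frequency-sweep conditions (Hz).  100 Hz is scheduled but conventionally
#: excluded from analysis because it is a harmonic of the 50 Hz line frequency.
FREQ_CONDITIONS_HZ: tuple[int, ...] = tuple(range(60, 101, 4))

#: Patch-size conditions (visual degrees, total patch including taper).
SIZE_CONDITIONS_DEG: tuple[int, ...] = tuple(range(2, 13))

#: Position grid: 3 rows x 5 columns, 6 degree centre spacing, origin at
#: fixation, +x right, +y up.  Row order lower, middle, upper.
POSITION_GRID_DEG: tuple[tuple[float, float], ...] = tuple(
    (float(x), float(y)) for y in (-6.0, 0.0, 6.0) for x in (-12.0, -6.0, 0.0, 6.0, 12.0)
)


@dataclass(frozen=True)
class Condition:
    """Stimulation parameters of a single trial."""

    freq_hz: float = 60.0
    size_deg: float = 6.0
    position_deg: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class DriveWaveform:
    """A tagging drive: luminance samples in [0, 1] under a ramp envelope.

    Attributes
    ----------
    freq_hz : drive frequency in Hz.
    sample_rate_hz : sampling rate of the waveform (projector refresh or
        acquisition rate).
    samples : luminance values, dimensionless in [0, 1].
    envelope : the modulation envelope in [0, 1]; 0 at the first and last
        sample, 1 over the plateau.
    train_duration_s : total train length in seconds.
    ramp_duration_s : duration of each half-Hanning ramp in seconds.
    t0_index : sample index of full-stimulation onset (the t = 0 convention).
    """

    freq_hz: float
    sample_rate_hz: float
    samples: np.ndarray
    envelope: np.ndarray
    train_duration_s: float
    ramp_duration_s: float
    t0_index: int
    baseline_luminance: float = 0.5
    modulation_depth: float = 1.0
    phase0: float = 0.0

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, t = 0 at full-stimulation onset."""
        n = self.samples.size
        return (np.arange(n) - self.t0_index) / self.sample_rate_hz

    @property
    def plateau_duration_s(self) -> float:
        """Duration at full amplitude, measured as plateau samples / rate."""
        return float(np.sum(self.envelope >= 1.0)) / self.sample_rate_hz

    def modulation(self) -> np.ndarray:
        """Zero-mean drive (samples minus the luminance baseline)."""
        return self.samples - self.baseline_luminance

    def to_tsv(self, path: str | Path) -> None:
        """Write (time, luminance, envelope) as TSV with a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            {"time_s": self.times_s, "luminance": self.samples, "envelope": self.envelope}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.9g")
        meta = {
            "freq_hz": self.freq_hz,
            "sample_rate_hz": self.sample_rate_hz,
            "train_duration_s": self.train_duration_s,
            "ramp_duration_s": self.ramp_duration_s,
            "t0_index": self.t0_index,
            "baseline_luminance": self.baseline_luminance,
            "modulation_depth": self.modulation_depth,
            "phase0": self.phase0,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _half_hanning_ramp(n_ramp: int) -> np.ndarray:
    """Rising half-Hanning ramp over ``n_ramp`` samples: sin^2(pi*i/(2*n))."""
    i = np.arange(n_ramp)
    return np.sin(np.pi * i / (2 * n_ramp)) ** 2


def make_drive_waveform(
    freq_hz: float,
    sample_rate_hz: float,
    train_duration_s: float = 1.4,
    ramp_duration_s: float = 0.2,
    baseline_luminance: float = 0.5,
    modulation_depth: float = 1.0,
    phase0: float = 0.0,
) -> DriveWaveform:
    """Build a sinusoidal tagging drive with half-Hanning on/off ramps.

    The luminance is ``baseline + 0.5 * depth * envelope(t) * sin(2*pi*f*t
    + phase0)`` where the envelope rises 0 -> 1 over ``ramp_duration_s`` as a
    half-Hanning window, sits at 1 over the plateau, and falls symmetrically
    at the end.  With the defaults (mid-grey baseline 0.5, depth 1.0) the
    drive spans the full black-to-white luminance range.

    Raises
    ------
    ValueError
        for non-positive durations, a plateau of non-positive length, a
        sampling rate violating the Nyquist criterion for ``freq_hz``, or a
        baseline/depth combination leaving the [0, 1] luminance range.
    """
    if train_duration_s <= 0 or ramp_duration_s <= 0:
        raise ValueError("train_duration_s and ramp_duration_s must be positive")
    if train_duration_s <= 2 * ramp_duration_s:
        raise ValueError(
            f"train ({train_duration_s} s) must exceed twice the ramp "
            f"({ramp_duration_s} s); no plateau would remain"
        )
    if freq_hz < 0:
        raise ValueError("freq_hz must be non-negative")
    if freq_hz > 0 and sample_rate_hz <= 2 * freq_hz:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz violates Nyquist for a "
            f"{freq_hz} Hz drive (needs > {2 * freq_hz} Hz)"
        )
    half = 0.5 * abs(modulation_depth)
    if baseline_luminance - half < -1e-12 or baseline_luminance + half > 1 + 1e-12:
        raise ValueError("baseline_luminance +/- depth/2 must stay within [0, 1]")

    n = int(round(train_duration_s * sample_rate_hz))
    n_ramp = int(round(ramp_duration_s * sample_rate_hz))
    env = np.ones(n)
    ramp = _half_hanning_ramp(n_ramp)
    env[:n_ramp] = ramp
    env[n - n_ramp:] = ramp[::-1]  # mirror: time-symmetric about the midpoint

    t = (np.arange(n) - n_ramp) / sample_rate_hz
    samples = baseline_luminance + 0.5 * modulation_depth * env * np.sin(
        2 * np.pi * freq_hz * t + phase0
    )
    return DriveWaveform(
        freq_hz=freq_hz,
        sample_rate_hz=sample_rate_hz,
        samples=samples,
        envelope=env,
        train_duration_s=train_duration_s,
        ramp_duration_s=ramp_duration_s,
        t0_index=n_ramp,
        baseline_luminance=baseline_luminance,
        modulation_depth=modulation_depth,
        phase0=phase0,
    )


@dataclass(frozen=True)
class TaperMask:
    """Radial amplitude mask for a circular stimulation patch.

    ``values`` is a 2D grid of amplitudes in [0, 1]: 1 inside the central
    plateau (``full_fraction`` of the patch diameter), raised-cosine falloff
    across the surrounding annulus, 0 at and beyond the patch edge.
    """

    patch_diameter_deg: float
    pixel_scale_deg: float
    full_fraction: float
    values: np.ndarray
    center_deg: tuple[float, float] = (0.0, 0.0)

    def radii(self) -> np.ndarray:
        """Radial distance of every grid cell from the patch centre (deg)."""
        n = self.values.shape[0]
        ax = (np.arange(n) - (n - 1) / 2) * self.pixel_scale_deg
        xx, yy = np.meshgrid(ax, ax)
        return np.hypot(xx, yy)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")
        meta = {
            "patch_diameter_deg": self.patch_diameter_deg,
            "pixel_scale_deg": self.pixel_scale_deg,
            "full_fraction": self.full_fraction,
            "center_deg": list(self.center_deg),
            "shape": list(self.values.shape),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def make_spatial_taper(
    patch_diameter_deg: float,
    pixel_scale_deg: float,
    full_fraction: float = 0.6,
    center_deg: tuple[float, float] = (0.0, 0.0),
) -> TaperMask:
    """Build the 2D spatial taper of a circular tagging patch.

    Full amplitude is delivered in a central disc spanning ``full_fraction``
    (default 60 %) of the total patch diameter; the surrounding annulus is
    tapered with a raised cosine down to zero at the patch edge, which hides
    the otherwise visible rim of the flickering patch.
    """
    if patch_diameter_deg <= 0:
        raise ValueError("patch_diameter_deg must be positive")
    if pixel_scale_deg <= 0:
        raise ValueError("pixel_scale_deg must be positive")
    if not 0 < full_fraction < 1:
        raise ValueError("full_fraction must lie strictly between 0 and 1")

    n = int(np.ceil(patch_diameter_deg / pixel_scale_deg))
    n += 1 - n % 2  # odd size so the grid has a centre pixel
    ax = (np.arange(n) - (n - 1) / 2) * pixel_scale_deg
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy)

    r_full = full_fraction * patch_diameter_deg / 2
    r_edge = patch_diameter_deg / 2
    with np.errstate(invalid="ignore"):
        ring = 0.5 * (1 + np.cos(np.pi * (r - r_full) / (r_edge - r_full)))
    values = np.where(r <= r_full, 1.0, np.where(r >= r_edge, 0.0, ring))
    return TaperMask(
        patch_diameter_deg=patch_diameter_deg,
        pixel_scale_deg=pixel_scale_deg,
        full_fraction=full_fraction,
        values=values,
        center_deg=center_deg,
    )


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial list of one experimental session.

    ``trials`` has columns block, condition_id, kind ('rft' or 'response'),
    freq_hz, size_deg, pos_x_deg, pos_y_deg.  Response trials (fixation-cross
    colour-change catch trials) are interspersed within each block and are
    excluded from analysis downstream.
    """

    session_type: SessionType
    trials: pd.DataFrame = field(repr=False)
    seed: int = 0

    def counts_per_condition(self, kind: str = "rft") -> pd.Series:
        sub = self.trials[self.trials["kind"] == kind]
        return sub.groupby("condition_id", sort=True).size()

    def response_fraction(self) -> float:
        return float((self.trials["kind"] == "response").mean())

    def conditions(self) -> list[Condition]:
        """Unique tagging conditions in condition-id order."""
        sub = self.trials[self.trials["kind"] == "rft"].drop_duplicates("condition_id")
        sub = sub.sort_values("condition_id")
        return [
            Condition(
                freq_hz=row.freq_hz,
                size_deg=row.size_deg,
                position_deg=(row.pos_x_deg, row.pos_y_deg),
            )
            for row in sub.itertuples()
        ]


# Session definitions: (n_blocks, reps of each condition per block,
# response trials per block).
_SESSION_DEFS = {
    SessionType.FREQ: dict(n_blocks=12, reps=3, n_response=11),
    SessionType.SIZE: dict(n_blocks=12, reps=3, n_response=11),
    SessionType.POSITION: dict(n_blocks=16, reps=2, n_response=15),
}


def _session_conditions(session_type: SessionType) -> list[dict]:
    if session_type == SessionType.FREQ:
        return [
            dict(condition_id=f"f{f:03d}", freq_hz=float(f), size_deg=10.0,
                 pos_x_deg=0.0, pos_y_deg=0.0)
            for f in FREQ_CONDITIONS_HZ
        ]
    if session_type == SessionType.SIZE:
        return [
            dict(condition_id=f"s{s:02d}", freq_hz=66.0, size_deg=float(s),
                 pos_x_deg=0.0, pos_y_deg=0.0)
            for s in SIZE_CONDITIONS_DEG
        ]
    if session_type == SessionType.POSITION:
        return [
            dict(condition_id=f"p{i:02d}", freq_hz=66.0, size_deg=10.0,
                 pos_x_deg=x, pos_y_deg=y)
            for i, (x, y) in enumerate(POSITION_GRID_DEG)
        ]
    raise ValueError(f"unknown session type: {session_type!r}")


def schedule_session(session_type: SessionType | str, seed: int = 0) -> TrialSchedule:
    """Build the seeded trial schedule of one session.

    FREQ: 12 blocks of 33 tagging trials (11 frequencies 60..100 Hz step 4,
    3 repetitions each) plus 11 response trials -> 36 tagging trials per
    frequency, response trials 25 % of the session.  SIZE: identical counts
    with 11 patch sizes (2..12 deg) at 66 Hz.  POSITION: 16 blocks of 45
    trials of which 30 are tagging trials (15 grid positions, 2 repetitions
    each) -> 32 tagging trials per position.

    The within-block trial order is a seeded pseudo-random permutation;
    identical seeds reproduce the schedule exactly.
    """
    try:
        session_type = SessionType(session_type)
    except ValueError as err:
        raise ValueError(f"unknown session type: {session_type!r}") from err

    spec = _SESSION_DEFS[session_type]
    conds = _session_conditions(session_type)
    if spec["n_response"] > len(conds):
        raise ValueError("more response trials than conditions per block")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for block in range(spec["n_blocks"]):
        block_rows = [
            dict(block=block, kind="rft", **c) for c in conds for _ in range(spec["reps"])
        ]
        # response trials carry a condition drawn without replacement so the
        # catch-trial stimulation spans the condition set evenly
        picks = rng.choice(len(conds), size=spec["n_response"], replace=False)
        block_rows += [dict(block=block, kind="response", **conds[j]) for j in picks]
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[k] for k in order)

    trials = pd.DataFrame(rows)
    trials.index.name = "trial"
    return TrialSchedule(session_type=session_type, trials=trials, seed=seed)
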