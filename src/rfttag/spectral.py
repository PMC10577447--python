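"""Power, cross-spectra, photodiode coherence, and time-frequency maps.

The tagging response is quantified as the magnitude-squared coherence
between each MEG sensor x(t) and the photodiode y(t),

    Coh_xy(f) = |C_xy(f)|^2 / (C_xx(f) * C_yy(f)),

where C_xy(f) is the trial-averaged cross-spectrum (the product of the
Fourier coefficients of x with the complex conjugate of those of y) and
C_xx = C_yy-style auto terms are the trial-averaged power spectra.
Coherence lies in [0, 1]; 1 means perfect phase alignment across trials.

Windowing conventions: spectra are computed on 1 s segments (a fixation
baseline at -1.2..-0.2 s and the full-stimulation interval 0..1 s) with a
single Hanning taper per trial, giving a 1 Hz bin spacing that places every
integer tagging frequency exactly on a DFT bin.  Time-frequency maps use a
500 ms Hanning-tapered window slid in 50 ms steps over 2-100 Hz in 2 Hz
steps.  All sample windows are half-open [start, stop) so a 1 s segment at
1000 Hz is exactly 1000 samples and adjacent segments never share a sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .synthmeg import EpochSet, SensorLayout

__all__ = [
    "SpectralEstimate",
    "TFRMap",
    "TrialCoefficients",
    "segment_epochs",
    "tapered_fourier",
    "trial_coefficients",
    "coherence_spectrum",
    "power_spectrum",
    "coherence_from_coeffs",
    "combine_planar_pairs",
    "tfr",
    "freq_index",
]

BASELINE_WINDOW_S = (-1.2, -0.2)
STIM_WINDOW_S = (0.0, 1.0)


@dataclass(frozen=True)
class SpectralEstimate:
    """Per-sensor power, cross-spectrum with the photodiode, and coherence."""

    freqs_hz: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)            # sensor x freq, >= 0
    cross: np.ndarray | None = field(repr=False)     # sensor x freq, complex
    coherence: np.ndarray | None = field(repr=False)  # sensor x freq in [0, 1]
    sensor_ids: list[str] = field(default_factory=list)
    n_trials: int = 0
    window_s: tuple[float, float] = STIM_WINDOW_S
    combined: bool = False

    def sensor_index(self, sensor_id: str) -> int:
        return self.sensor_ids.index(sensor_id)

    def coherence_at(self, freq_hz: float) -> np.ndarray:
        """Coherence of every sensor at the bin containing ``freq_hz``."""
        return self.coherence[:, freq_index(self.freqs_hz, freq_hz)]

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV (sensor, freq_hz, power[, coherence])."""
        path = Path(path)
        ns, nf = self.power.shape
        df = pd.DataFrame({
            "sensor": np.repeat(self.sensor_ids, nf),
            "freq_hz": np.tile(self.freqs_hz, ns),
            "power": self.power.ravel(),
        })
        if self.coherence is not None:
            df["coherence"] = self.coherence.ravel()
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        meta = {"n_trials": self.n_trials, "window_s": list(self.window_s),
                "combined": self.combined}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class TFRMap:
    """Sliding-window time-frequency map (coherence or power)."""

    freqs_hz: np.ndarray = field(repr=False)
    times_s: np.ndarray = field(repr=False)   # window centres
    values: np.ndarray = field(repr=False)    # sensor x freq x time
    sensor_ids: list[str] = field(default_factory=list)
    measure: str = "coherence"
    window_length_s: float = 0.5

    def to_tsv(self, path: str | Path) -> None:
        ns, nf, nt = self.values.shape
        df = pd.DataFrame({
            "sensor": np.repeat(self.sensor_ids, nf * nt),
            "freq_hz": np.tile(np.repeat(self.freqs_hz, nt), ns),
            "time_s": np.tile(self.times_s, ns * nf),
            self.measure: self.values.ravel(),
        })
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass(frozen=True)
class TrialCoefficients:
    """Per-trial tapered Fourier coefficients of one analysis window.

    Keeping single-trial coefficients (rather than the averaged spectra)
    lets permutation procedures recompute coherence under relabelled trial
    groups.  ``coeffs`` is trials x channels x freqs, complex.
    """

    coeffs: np.ndarray = field(repr=False)
    freqs_hz: np.ndarray = field(repr=False)
    channel_ids: list[str]
    photodiode_channel_id: str
    window_s: tuple[float, float]

    @property
    def photodiode_index(self) -> int:
        return self.channel_ids.index(self.photodiode_channel_id)

    def select_trials(self, mask: np.ndarray) -> "TrialCoefficients":
        return replace(self, coeffs=self.coeffs[mask])

    def sensor_indices(self) -> np.ndarray:
        di = self.photodiode_index
        return np.array([i for i in range(len(self.channel_ids)) if i != di])


def _window_slice(times_s: np.ndarray, fs: float, window_s: tuple[float, float]) -> slice:
    """Half-open [start, stop) sample window on the epoch time axis."""
    start_s, stop_s = window_s
    if start_s < times_s[0] - 1e-9 or stop_s > times_s[-1] + 1 / fs + 1e-9:
        raise ValueError(f"window {window_s} not covered by epoch "
                         f"[{times_s[0]:g}, {times_s[-1]:g}]")
    i0 = int(round((start_s - times_s[0]) * fs))
    n = int(round((stop_s - start_s) * fs))
    return slice(i0, i0 + n)


def segment_epochs(
    epochs: EpochSet,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    stim_window_s: tuple[float, float] = STIM_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the baseline and full-stimulation segments out of every trial.

    Returns two trials x channels x samples arrays of equal length (1 s at
    1000 Hz -> exactly 1000 samples each, half-open windows).
    """
    fs = epochs.sample_rate_hz
    sl_base = _window_slice(epochs.times_s, fs, baseline_window_s)
    sl_stim = _window_slice(epochs.times_s, fs, stim_window_s)
    if (sl_base.stop - sl_base.start) != (sl_stim.stop - sl_stim.start):
        raise ValueError("baseline and stimulation windows differ in length")
    return epochs.data[:, :, sl_base], epochs.data[:, :, sl_stim]


def tapered_fourier(segment: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-tapered DFT of ... x samples data (one taper per trial).

    Returns ``(coeffs, freqs_hz)`` where the frequency grid is k/T Hz for a
    T-second segment.  Coefficients are normalized by the taper RMS
    (``1/sqrt(sum(w^2))``) so that the one-sided sum of ``c_k |X_k|^2``
    (c_k = 2 except at DC and Nyquist) equals the mean power of the tapered
    signal — the Parseval identity under this convention.
    """
    segment = np.asarray(segment)
    n = segment.shape[-1]
    if n == 0:
        raise ValueError("empty segment")
    w = hann(n, sym=False)
    coeffs = np.fft.rfft(segment * w, axis=-1) / np.sqrt(n * np.sum(w**2))
    freqs = np.fft.rfftfreq(n, 1 / sample_rate_hz)
    return coeffs, freqs


def trial_coefficients(epochs: EpochSet, window_s: tuple[float, float]) -> TrialCoefficients:
    """Tapered Fourier coefficients of one analysis window of an EpochSet."""
    fs = epochs.sample_rate_hz
    sl = _window_slice(epochs.times_s, fs, window_s)
    coeffs, freqs = tapered_fourier(epochs.data[:, :, sl], fs)
    return TrialCoefficients(coeffs=coeffs, freqs_hz=freqs,
                             channel_ids=list(epochs.channel_ids),
                             photodiode_channel_id=epochs.photodiode_channel_id,
                             window_s=window_s)


def freq_index(freqs_hz: np.ndarray, target_hz: float,
               tol_hz: float | None = None) -> int:
    """Nearest-bin lookup with an explicit tolerance.

    ``tol_hz`` defaults to half the bin spacing and is clamped to at most
    that; a target farther from its nearest bin raises instead of silently
    rounding.
    """
    idx = int(np.argmin(np.abs(freqs_hz - target_hz)))
    df = float(freqs_hz[1] - freqs_hz[0]) if freqs_hz.size > 1 else np.inf
    tol = df / 2 if tol_hz is None else min(tol_hz, df / 2)
    if abs(freqs_hz[idx] - target_hz) > tol + 1e-9:
        raise ValueError(f"{target_hz} Hz is {abs(freqs_hz[idx] - target_hz):g} Hz "
                         f"off the frequency grid (spacing {df:g} Hz, "
                         f"tolerance {tol:g} Hz)")
    return idx


def power_spectrum(coeffs: np.ndarray) -> np.ndarray:
    """Trial-averaged power |X_k(f)|^2 per channel (trials x ch x freq in)."""
    return np.mean(np.abs(coeffs) ** 2, axis=0)


def coherence_from_coeffs(meg_coeffs: np.ndarray, diode_coeffs: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Coherence and cross-spectrum from per-trial Fourier coefficients.

    ``meg_coeffs`` is trials x sensors x freqs, ``diode_coeffs`` trials x
    freqs.  Bins where either signal has zero power yield NaN (coherence is
    undefined there, not zero).
    """
    if meg_coeffs.shape[0] < 2:
        raise ValueError("coherence needs at least 2 trials "
                         "(a single trial gives identically 1)")
    cross = np.mean(meg_coeffs * np.conj(diode_coeffs[:, None, :]), axis=0)
    p_meg = np.mean(np.abs(meg_coeffs) ** 2, axis=0)
    p_diode = np.mean(np.abs(diode_coeffs) ** 2, axis=0)
    denom = p_meg * p_diode[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / denom
    coh = np.where(denom > 0, coh, np.nan)
    # the estimator is bounded by Cauchy-Schwarz; clip float round-off only
    return np.clip(coh, 0.0, 1.0), cross


def coherence_spectrum(coeffs: TrialCoefficients) -> SpectralEstimate:
    """Photodiode coherence and power spectra from trial coefficients."""
    di = coeffs.photodiode_index
    si = coeffs.sensor_indices()
    meg = coeffs.coeffs[:, si, :]
    diode = coeffs.coeffs[:, di, :]
    coh, cross = coherence_from_coeffs(meg, diode)
    return SpectralEstimate(
        freqs_hz=coeffs.freqs_hz,
        power=power_spectrum(meg),
        cross=cross,
        coherence=coh,
        sensor_ids=[coeffs.channel_ids[i] for i in si],
        n_trials=coeffs.coeffs.shape[0],
        window_s=coeffs.window_s,
    )


def combine_planar_pairs(estimate: SpectralEstimate, layout: SensorLayout) -> SpectralEstimate:
    """Merge co-located gradiometer pairs: sum power, average coherence.

    Magnetometer rows pass through unchanged.  The cross-spectrum has no
    meaningful pair combination and is dropped from the combined estimate.
    """
    if estimate.combined:
        raise ValueError("estimate is already pair-combined")
    ch = layout.channels.set_index("id")
    missing = [s for s in estimate.sensor_ids if s not in ch.index]
    if missing:
        raise ValueError(f"sensors not in layout: {missing}")

    idx = {s: i for i, s in enumerate(estimate.sensor_ids)}
    new_ids: list[str] = []
    power_rows: list[np.ndarray] = []
    coh_rows: list[np.ndarray] = []
    grads = ch.loc[[s for s in estimate.sensor_ids if ch.at[s, "type"] == "grad"]]
    for pair_id, members in grads.groupby("pair_id", sort=True):
        if len(members) != 2:
            raise ValueError(f"gradiometer pair {pair_id} has {len(members)} member(s)")
        i, j = (idx[s] for s in members.index)
        new_ids.append(f"P{pair_id:02d}")
        power_rows.append(estimate.power[i] + estimate.power[j])
        if estimate.coherence is not None:
            coh_rows.append(0.5 * (estimate.coherence[i] + estimate.coherence[j]))
    for s in estimate.sensor_ids:
        if ch.at[s, "type"] == "mag":
            new_ids.append(s)
            power_rows.append(estimate.power[idx[s]])
            if estimate.coherence is not None:
                coh_rows.append(estimate.coherence[idx[s]])

    return replace(
        estimate,
        power=np.array(power_rows),
        cross=None,
        coherence=np.array(coh_rows) if coh_rows else None,
        sensor_ids=new_ids,
        combined=True,
    )


def tfr(
    epochs: EpochSet,
    measure: Literal["coherence", "power"] = "coherence",
    freqs_hz: np.ndarray | None = None,
    window_length_s: float = 0.5,
    step_s: float = 0.05,
    baseline_window_s: tuple[float, float] | None = None,
) -> TFRMap:
    """Sliding-window time-frequency map of coherence or power.

    Defaults follow the sensor-level analysis conventions: 2-100 Hz in 2 Hz
    steps, 500 ms Hanning-tapered windows shifted in 50 ms steps.  With
    ``baseline_window_s`` set, the mean over window centres inside that
    interval is subtracted per sensor and frequency.
    """
    fs = epochs.sample_rate_hz
    if freqs_hz is None:
        freqs_hz = np.arange(2.0, 100.0 + 1e-9, 2.0)
    n_win = int(round(window_length_s * fs))
    if n_win > epochs.times_s.size:
        raise ValueError("epoch shorter than one analysis window")
    native = np.fft.rfftfreq(n_win, 1 / fs)
    bins = np.array([freq_index(native, f) for f in freqs_hz])

    half = window_length_s / 2
    t0, t1 = epochs.times_s[0], epochs.times_s[-1] + 1 / fs
    centers = np.arange(np.ceil((t0 + half) / step_s) * step_s,
                        t1 - half + 1e-9, step_s)
    di = epochs.photodiode_index
    si = [i for i in range(len(epochs.channel_ids)) if i != di]

    vals = np.empty((len(si), freqs_hz.size, centers.size))
    for k, c in enumerate(centers):
        sl = _window_slice(epochs.times_s, fs, (c - half, c + half))
        coeffs, _ = tapered_fourier(epochs.data[:, :, sl], fs)
        if measure == "power":
            vals[:, :, k] = power_spectrum(coeffs[:, si, :])[:, bins]
        elif measure == "coherence":
            coh, _ = coherence_from_coeffs(coeffs[:, si, :], coeffs[:, di, :])
            vals[:, :, k] = coh[:, bins]
        else:
            raise ValueError(f"unknown measure: {measure!r}")

    if baseline_window_s is not None:
        b0, b1 = baseline_window_s
        in_base = (centers >= b0 - 1e-9) & (centers <= b1 + 1e-9)
        if not in_base.any():
            raise ValueError("baseline window contains no TFR window centres")
        vals = vals - vals[:, :, in_base].mean(axis=2, keepdims=True)

    return TFRMap(freqs_hz=freqs_hz, times_s=centers, values=vals,
                  sensor_ids=[epochs.channel_ids[i] for i in si],
                  measure=measure, window_length_s=window_length_s)
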