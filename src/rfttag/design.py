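"""Design-check arithmetic for multi-stimulus tagging experiments.

When several items are tagged simultaneously, two constraints govern the
choice of frequencies: the spectral resolution of the analysis window
(frequencies closer than 1/dT Hz cannot be separated in a dT-second
window), and intermodulation components |m*f1 +/- n*f2| produced by any
nonlinearity in the response, which must not collide with a tagging
frequency or a band of interest.
"""

from __future__ import annotations

__all__ = ["min_tag_separation_hz", "intermodulation_freqs"]


def min_tag_separation_hz(analysis_window_s: float) -> float:
    """Minimal distinguishable tagging-frequency separation, 1/dT Hz.

    A 0.2 s analysis window resolves frequencies no closer than 5 Hz; a
    0.5 s window no closer than 2 Hz.
    """
    if analysis_window_s <= 0:
        raise ValueError("analysis window must be positive")
    return 1.0 / analysis_window_s


def intermodulation_freqs(f1_hz: float, f2_hz: float, max_order: int = 2) -> list[float]:
    """Intermodulation frequencies |m*f1 +/- n*f2| up to a given order.

    Order = m + n with m, n >= 1.  For f1 = 55, f2 = 60 the lowest
    difference component is f2 - f1 = 5 Hz.  Returned sorted, deduplicated.
    """
    if f1_hz < 0 or f2_hz < 0:
        raise ValueError("frequencies must be non-negative")
    if max_order < 2:
        raise ValueError("max_order must be at least 2")
    out = set()
    for m in range(1, max_order):
        for n in range(1, max_order - m + 1):
            out.add(abs(m * f1_hz - n * f2_hz))
            out.add(m * f1_hz + n * f2_hz)
    return sorted(out)
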