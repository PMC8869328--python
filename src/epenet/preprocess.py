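"""Notch filtering and band-pass decomposition of EEG segments.

Filtering follows the conventional resting-state EEG recipe: a 50 Hz notch
for power-line interference, then a third-order Butterworth band-pass into
the four analysis bands (delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz).
Both filters are applied zero-phase (forward–backward) so that phase-based
connectivity downstream is not biased by filter group delay; the effective
magnitude response is the square of the single-pass response.  Filtering is
strictly per-channel and never mixes channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandFilteredSegment",
    "notch_filter",
    "bandpass",
    "trim_edges",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz with 0 < lo < hi."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    def validate_against(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name} [{self.lo}, {self.hi}] Hz exceeds Nyquist {fs / 2} Hz"
            )


#: The four conventional analysis bands.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
}


@dataclass(frozen=True)
class BandFilteredSegment:
    """An EEG segment restricted to one frequency band."""

    subject_id: str
    group: str
    data: np.ndarray  # channels x samples
    fs: float
    channel_labels: tuple[str, ...]
    band: BandDefinition

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def notch_filter(seg, freq: float = 50.0, quality: float = 30.0):
    """Zero-phase IIR notch at ``freq`` Hz (second-order, Q=30 by default).

    Returns a segment of the same type with all labels and dimensions
    unchanged; only a narrow band around ``freq`` is attenuated.
    """
    if not (0 < freq < seg.fs / 2):
        raise ValueError(f"notch frequency {freq} Hz must lie in (0, {seg.fs / 2}) Hz")
    b, a = signal.iirnotch(freq, quality, fs=seg.fs)
    filtered = signal.filtfilt(b, a, np.asarray(seg.data, dtype=float), axis=-1)
    return replace(seg, data=filtered)


def bandpass(seg, band: BandDefinition) -> BandFilteredSegment:
    """Third-order Butterworth band-pass, applied forward–backward per channel."""
    band.validate_against(seg.fs)
    sos = signal.butter(3, [band.lo, band.hi], btype="bandpass", fs=seg.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(seg.data, dtype=float), axis=-1)
    return BandFilteredSegment(
        subject_id=seg.subject_id,
        group=seg.group,
        data=filtered,
        fs=seg.fs,
        channel_labels=tuple(seg.channel_labels),
        band=band,
    )


def trim_edges(seg, seconds: float = 1.0):
    """Drop the first and last ``seconds`` of a (filtered) segment.

    Used before connectivity estimation to discard forward–backward filter
    transients at the segment boundaries.
    """
    if seconds <= 0:
        return seg
    k = int(round(seconds * seg.fs))
    if 2 * k >= seg.data.shape[-1]:
        raise ValueError(f"trim of {seconds} s removes the whole {seg.data.shape[-1]}-sample segment")
    return replace(seg, data=seg.data[..., k:-k])
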