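"""Seeded synthetic resting-state EEG cohorts with group/band coupling structure.

The clinical recordings the analysis was designed around are not publicly
deposited, so every downstream stage is exercised on a synthetic cohort whose
*statistical* structure mirrors the reported group contrasts: three groups
(SCI, MCI, AD) whose band-specific inter-channel coupling is strongest for
MCI in delta and strongest for SCI in alpha/beta.

Generation model, per subject and per band
------------------------------------------
Each band has one band-wide global driver plus three regional latent sources
(anterior / central / posterior), all band-pass-filtered unit-variance
Gaussian-noise oscillators.  Channels are ordered anterior -> posterior and
assigned a position t in [0, 1]; each channel blends the regional sources
with triangular weights centred on its position, so nearby channels share
local sources strongly and distant channels share only the global driver.

With ``c = band_coupling[(group, band)]`` the per-channel signal splits its
variance into three shares,

    global    G(c) = c^1.8                      (band-wide driver)
    local     L(c) = 2.1 c^0.6 (1 - c)^2        (regional blend)
    intrinsic 1 - G - L                         (independent channel noise)

so that c = 0 gives fully independent channels, c = 1 gives all channels an
identical (delayed) copy of the global driver, and intermediate coupling
leaves a strong short-range backbone: low-coupling groups route information
through chains of neighbouring electrodes (many shortest-path hops, weak
triangles) while high-coupling groups connect every pair directly (few
hops, dense triangles) — the qualitative network contrast the group presets
encode.  Each channel's shared content is delayed by a fixed fractional lag
(0–6 ms, a cohort-level property drawn once from the master seed) so
phase-lag-based connectivity is non-degenerate.  A second, independent knob
— ``band_amplitude[(group, band)]`` — scales each group's signal level per
band, emulating the shift of EEG power toward slow rhythms with cognitive
decline; amplitude carries the information-content (entropy) contrast while
coupling carries the coherence/phase contrast.  Broadband Gaussian noise of
scale ``noise_sd`` is added on top.  All randomness derives from a single
master seed via ``numpy.random.SeedSequence`` spawning: child 0 drives the
cohort-level lags, children 1..n_subjects the per-subject streams, so
cohorts are bit-identical for identical configurations.

The generator emulates coupling structure only — not 1/f spectra, artifacts,
or realistic topographies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from epenet.montage import MONTAGE_30
from epenet.preprocess import DEFAULT_BANDS, BandDefinition

__all__ = [
    "CohortConfig",
    "EEGSegment",
    "CohortParseError",
    "DEFAULT_BAND_COUPLING",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

GROUPS: tuple[str, ...] = ("SCI", "MCI", "AD")

#: Default preset: delta coupling MCI > AD > SCI, alpha/beta SCI > AD > MCI
#: (gaps >= 0.15), theta intermediate with the same high-frequency ordering.
DEFAULT_BAND_COUPLING: dict[tuple[str, str], float] = {
    ("SCI", "delta"): 0.25, ("AD", "delta"): 0.45, ("MCI", "delta"): 0.70,
    ("SCI", "theta"): 0.50, ("AD", "theta"): 0.45, ("MCI", "theta"): 0.40,
    ("SCI", "alpha"): 0.75, ("AD", "alpha"): 0.50, ("MCI", "alpha"): 0.25,
    ("SCI", "beta"): 0.70, ("AD", "beta"): 0.45, ("MCI", "beta"): 0.20,
}

#: Band-specific signal amplitude (the "complexity"/activity knob): cognitive
#: decline shifts EEG power toward the slow bands — MCI/AD carry more delta
#: and less alpha/beta activity than SCI, with MCI most accentuated.
DEFAULT_BAND_AMPLITUDE: dict[tuple[str, str], float] = {
    ("SCI", "delta"): 0.50, ("AD", "delta"): 1.00, ("MCI", "delta"): 2.00,
    ("SCI", "theta"): 1.20, ("AD", "theta"): 1.00, ("MCI", "theta"): 0.85,
    ("SCI", "alpha"): 2.00, ("AD", "alpha"): 1.00, ("MCI", "alpha"): 0.50,
    ("SCI", "beta"): 2.00, ("AD", "beta"): 1.00, ("MCI", "beta"): 0.50,
}

# Shape of the regional (short-range) variance share: strong at low-to-mid
# coupling (information then travels along chains of neighbouring channels)
# and decaying toward both extremes so the c=0 independence and c=1
# common-source limits stay exact.
_LOCAL_SCALE = 2.1
_LOCAL_RISE = 0.6
_LOCAL_DECAY = 2.0
_GLOBAL_EXP = 1.8
# Positions of the three regional source centres along the
# anterior->posterior axis, and the half-width of their triangular footprint.
_REGION_CENTERS = (0.0, 0.5, 1.0)
_REGION_WIDTH = 0.5
# Maximum per-channel fractional lag (seconds) applied to shared sources.
_MAX_LAG_S = 0.006


def _coupling_shares(c: float) -> tuple[float, float, float]:
    """(global, local, intrinsic) variance shares for coupling c in [0, 1]."""
    local = _LOCAL_SCALE * c**_LOCAL_RISE * (1.0 - c) ** _LOCAL_DECAY
    glob = c**_GLOBAL_EXP
    return glob, local, 1.0 - glob - local


def _blend_weights(n_channels: int) -> np.ndarray:
    """(n_channels, 3) unit-norm triangular blend of the regional sources."""
    t = np.linspace(0.0, 1.0, n_channels) if n_channels > 1 else np.array([0.5])
    w = np.maximum(0.0, 1.0 - np.abs(t[:, None] - np.array(_REGION_CENTERS)[None, :]) / _REGION_WIDTH)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    return w / np.where(norms > 0, norms, 1.0)


def _fractional_delay(x: np.ndarray, tau_samples: float) -> np.ndarray:
    """Delay a signal by a (possibly fractional) number of samples via FFT.

    Circular; callers pass padded signals and crop the interior.
    """
    n = len(x)
    freqs = np.fft.rfftfreq(n)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * tau_samples), n)


def _default_group_sizes() -> dict[str, int]:
    return {"SCI": 22, "MCI": 52, "AD": 28}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``band_coupling`` maps ``(group, band_name)`` to a mixing weight in
    [0, 1]: the fraction of each channel's band-limited content drawn from
    its regional shared source.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_channels: int = 30
    channel_labels: tuple[str, ...] = MONTAGE_30
    fs: float = 256.0
    segment_seconds: float = 20.0
    band_coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_COUPLING)
    )
    band_amplitude: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDE)
    )
    bands: dict[str, BandDefinition] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    noise_sd: float = 0.3
    segments_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        labels = tuple(self.channel_labels)
        if len(labels) != self.n_channels:
            raise ValueError(
                f"channel_labels has {len(labels)} entries, expected n_channels={self.n_channels}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel_labels contains duplicates")
        hi_edge = max(b.hi for b in self.bands.values())
        if self.fs <= 2 * hi_edge:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge ({hi_edge} Hz)")
        for b in self.bands.values():
            b.validate_against(self.fs)
        for (g, bname), c in self.band_coupling.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"band_coupling[{(g, bname)}]={c} outside [0, 1]")
        for (g, bname), a in self.band_amplitude.items():
            if a <= 0:
                raise ValueError(f"band_amplitude[{(g, bname)}]={a} must be positive")
        if self.segments_per_subject < 1:
            raise ValueError("segments_per_subject must be >= 1")
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_seconds))

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class EEGSegment:
    """One labelled multichannel EEG window (channels x samples)."""

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class CohortParseError(ValueError):
    """Raised when an on-disk cohort is malformed; names the offending field."""


def _band_sos(band: BandDefinition, fs: float):
    return signal.butter(3, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def _band_noise(rng: np.random.Generator, sos, n: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise of length n."""
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * 256))[256:-256]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_cohort(config: CohortConfig) -> list[EEGSegment]:
    """Generate one (or more) segments per subject under ``config``.

    Deterministic: identical configs (including seed) produce bit-identical
    cohorts.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(1 + config.n_subjects)
    lag_rng = np.random.default_rng(children[0])
    lags = lag_rng.uniform(0.0, _MAX_LAG_S, size=config.n_channels) * config.fs  # samples

    n = config.n_samples
    pad = n // 2  # generate longer, crop the interior after circular delays
    total = n + 2 * pad
    sos_by_band = {name: _band_sos(b, config.fs) for name, b in config.bands.items()}
    blend = _blend_weights(config.n_channels)  # (n_channels, 3)

    segments: list[EEGSegment] = []
    subj_idx = 0
    for group in config.group_sizes:
        for k in range(config.group_sizes[group]):
            rng = np.random.default_rng(children[1 + subj_idx])
            subject_id = f"{group}-{k + 1:03d}"
            for s in range(config.segments_per_subject):
                data = np.zeros((config.n_channels, n))
                for bname, sos in sos_by_band.items():
                    c = config.band_coupling.get((group, bname), 0.0)
                    amp = config.band_amplitude.get((group, bname), 1.0)
                    g_share, l_share, n_share = _coupling_shares(c)
                    g = _band_noise(rng, sos, total)
                    locals_ = np.stack([_band_noise(rng, sos, total) for _ in range(3)])
                    for ch in range(config.n_channels):
                        shared = np.sqrt(g_share) * g + np.sqrt(l_share) * (
                            blend[ch] @ locals_
                        )
                        if g_share + l_share > 0:
                            shared = _fractional_delay(shared, lags[ch])
                        idio = _band_noise(rng, sos, n)
                        data[ch] += amp * (shared[pad : pad + n] + np.sqrt(n_share) * idio)
                data += config.noise_sd * rng.standard_normal(data.shape)
                sid = subject_id if config.segments_per_subject == 1 else f"{subject_id}-s{s + 1}"
                segments.append(
                    EEGSegment(
                        subject_id=sid,
                        group=group,
                        data=data,
                        fs=config.fs,
                        channel_labels=config.channel_labels,
                    )
                )
            subj_idx += 1
    return segments


# ---------------------------------------------------------------------------
# On-disk format: one delimited text matrix per segment + a JSON manifest.
# ---------------------------------------------------------------------------

def write_cohort(segments: list[EEGSegment], path: str | Path) -> Path:
    """Write a cohort as per-segment CSV matrices plus ``manifest.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, seg in enumerate(segments):
        fname = f"segment_{i:04d}.csv"
        np.savetxt(path / fname, seg.data, delimiter=",", fmt="%.10e")
        entries.append(
            {
                "subject_id": seg.subject_id,
                "group": seg.group,
                "fs": seg.fs,
                "channel_labels": list(seg.channel_labels),
                "n_samples": seg.n_samples,
                "file": fname,
            }
        )
    (path / "manifest.json").write_text(json.dumps({"segments": entries}, indent=1))
    return path


def read_cohort(path: str | Path) -> list[EEGSegment]:
    """Read a cohort written by :func:`write_cohort`; lossless round-trip."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise CohortParseError(f"manifest.json not found under {path}")
    try:
        manifest = json.loads(manifest_file.read_text())
    except json.JSONDecodeError as e:
        raise CohortParseError(f"manifest.json is not valid JSON: {e}") from e
    if "segments" not in manifest:
        raise CohortParseError("manifest.json: missing field 'segments'")

    segments = []
    for entry in manifest["segments"]:
        for key in ("subject_id", "group", "fs", "channel_labels", "n_samples", "file"):
            if key not in entry:
                raise CohortParseError(f"manifest entry missing field '{key}': {entry}")
        labels = entry["channel_labels"]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise CohortParseError(f"duplicated channel label(s) {dup} in segment {entry['subject_id']}")
        try:
            data = np.loadtxt(path / entry["file"], delimiter=",", ndmin=2)
        except ValueError as e:
            raise CohortParseError(
                f"segment {entry['subject_id']}: malformed data rows "
                f"(expected {entry['n_samples']} samples per row): {e}"
            ) from e
        if data.shape[0] != len(labels):
            raise CohortParseError(
                f"segment {entry['subject_id']}: {data.shape[0]} rows, expected {len(labels)} channels"
            )
        if data.shape[1] != entry["n_samples"]:
            raise CohortParseError(
                f"segment {entry['subject_id']}: row has {data.shape[1]} samples, "
                f"expected {entry['n_samples']}"
            )
        segments.append(
            EEGSegment(
                subject_id=entry["subject_id"],
                group=entry["group"],
                data=data,
                fs=float(entry["fs"]),
                channel_labels=tuple(labels),
            )
        )
    return segments
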