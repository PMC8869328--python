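"""Pairwise functional connectivity: PLI, magnitude-squared coherence,
and assembly of weighted adjacency matrices.

Phase lag index (PLI)
    ``PLI = |mean_t sign(sin(phi_x(t) - phi_y(t)))|`` — the asymmetry of the
    instantaneous phase-difference distribution, with phases taken from the
    analytic (Hilbert) signal of each band-filtered channel.  PLI is 0 for
    phase differences centred around 0 mod pi (so it discards zero-lag,
    volume-conduction-like coupling) and 1 for perfect non-zero-lag locking.

Magnitude-squared coherence (MSC)
    Welch-style estimate ``|<X Y*>|^2 / (<|X|^2><|Y|^2>)`` over M overlapping
    windows, averaged over the discrete frequencies inside the analysis band
    to give one scalar per pair per band.

Both measures are bounded in [0, 1].  Adjacency matrices are symmetric with
a zero diagonal that is structurally excluded from all downstream analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import signal

from epenet.preprocess import BandDefinition

__all__ = [
    "AdjacencyMatrix",
    "DegenerateSignalError",
    "compute_pli",
    "compute_msc",
    "pairwise_matrix",
    "group_average",
    "mean_offdiagonal",
]


class DegenerateSignalError(ValueError):
    """Raised for inputs with undefined phase/spectrum (e.g. constant signals)."""


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric nonnegative electrode x electrode connectivity matrix.

    The diagonal is stored as 0 and carries no meaning; every downstream
    computation ignores it.
    """

    values: np.ndarray
    measure: str
    band: BandDefinition
    channel_labels: tuple[str, ...]
    tag: str = ""  # subject_id or group label
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} channel labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency matrix must be symmetric")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and off.min() < -1e-12:
            raise ValueError("adjacency weights must be nonnegative")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    def to_csv(self, path: str | Path) -> Path:
        """Write as labelled CSV plus a JSON sidecar with the metadata."""
        import pandas as pd

        path = Path(path)
        labels = list(self.channel_labels)
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path, float_format="%.10g")
        sidecar = {
            "measure": self.measure,
            "band": {"name": self.band.name, "lo": self.band.lo, "hi": self.band.hi},
            "tag": self.tag,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "AdjacencyMatrix":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        band = BandDefinition(**sidecar["band"])
        meta = {k: v for k, v in sidecar.items() if k not in ("measure", "band", "tag")}
        return cls(
            values=df.to_numpy(),
            measure=sidecar["measure"],
            band=band,
            channel_labels=tuple(df.columns),
            tag=sidecar.get("tag", ""),
            meta=meta,
        )


def _instantaneous_phase(x: np.ndarray) -> np.ndarray:
    return np.angle(signal.hilbert(x))


def compute_pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index between two equal-length band-filtered channels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("compute_pli expects two equal-length 1-D signals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant signal: instantaneous phase undefined")
    dphi = _instantaneous_phase(x) - _instantaneous_phase(y)
    return float(abs(np.mean(np.sign(np.sin(dphi)))))


def compute_msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> float:
    """Band-averaged magnitude-squared coherence of two channels.

    The signals are cut into Welch windows of ``window_seconds`` with the
    given overlap; coherence is computed per frequency and then averaged
    arithmetically over the discrete frequencies inside ``band``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("compute_msc expects two equal-length 1-D signals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant signal: coherence undefined")
    nperseg = int(round(window_seconds * fs))
    noverlap = int(round(overlap_fraction * nperseg))
    step = nperseg - noverlap
    n_windows = 1 + max(0, (len(x) - nperseg)) // step if len(x) >= nperseg else 0
    if n_windows < 2:
        raise ValueError(
            f"need >= 2 Welch windows (got {n_windows}); coherence of one segment is trivially 1"
        )
    f, cxy = signal.coherence(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    in_band = (f >= band.lo) & (f <= band.hi)
    if not np.any(in_band):
        raise ValueError(f"no spectral bins inside band {band.name} [{band.lo}, {band.hi}] Hz")
    return float(np.mean(cxy[in_band]))


def pairwise_matrix(
    seg,
    measure_fn: Callable[[np.ndarray, np.ndarray], float],
    measure: str,
    tag: str | None = None,
) -> AdjacencyMatrix:
    """Apply ``measure_fn`` to all n(n-1)/2 unordered channel pairs.

    The strict upper triangle is filled and mirrored; the diagonal is 0 and
    excluded from analysis.  A failure on any pair is re-raised with the
    offending channel pair named.
    """
    data = seg.data
    n = data.shape[0]
    if n < 2:
        raise ValueError("pairwise connectivity needs at least 2 channels")
    values = np.zeros((n, n))
    labels = seg.channel_labels
    for i in range(n):
        for j in range(i + 1, n):
            try:
                w = measure_fn(data[i], data[j])
            except Exception as e:
                raise RuntimeError(
                    f"{measure} failed on pair ({labels[i]}, {labels[j]}): {e}"
                ) from e
            values[i, j] = values[j, i] = w
    return AdjacencyMatrix(
        values=values,
        measure=measure,
        band=seg.band,
        channel_labels=labels,
        tag=tag if tag is not None else seg.subject_id,
    )


def group_average(matrices: list[AdjacencyMatrix], group: str | None = None) -> AdjacencyMatrix:
    """Element-wise mean of subject adjacency matrices of one group."""
    if not matrices:
        raise ValueError("group_average of an empty list")
    first = matrices[0]
    for m in matrices[1:]:
        if m.measure != first.measure:
            raise ValueError(f"mixed measures: {m.measure} vs {first.measure}")
        if m.band != first.band:
            raise ValueError(f"mixed bands: {m.band.name} vs {first.band.name}")
        if m.channel_labels != first.channel_labels:
            raise ValueError("mixed channel label sets")
    mean = np.mean([m.values for m in matrices], axis=0)
    return AdjacencyMatrix(
        values=mean,
        measure=first.measure,
        band=first.band,
        channel_labels=first.channel_labels,
        tag=group if group is not None else first.tag,
        meta={"n_subjects": len(matrices)},
    )


def mean_offdiagonal(A: AdjacencyMatrix | np.ndarray) -> float:
    """Mean connectivity over the off-diagonal entries."""
    v = A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    n = v.shape[0]
    return float(v[~np.eye(n, dtype=bool)].mean())
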