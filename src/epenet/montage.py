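"""The 30-electrode 10–20 montage used throughout the analysis.

Electrodes are ordered anterior → posterior, the order in which they appear
on every adjacency matrix row/column and in every per-node table.
"""

from __future__ import annotations

# Anterior-to-posterior ordering of the 30 scalp positions.
MONTAGE_30: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

# Coarse anterior / central / posterior split, used both by the synthetic
# generator (regional latent sources) and by module-composition reports.
_REGION_OF = {}
for _lab in MONTAGE_30[:12]:
    _REGION_OF[_lab] = "anterior"
for _lab in MONTAGE_30[12:22]:
    _REGION_OF[_lab] = "central"
for _lab in MONTAGE_30[22:]:
    _REGION_OF[_lab] = "posterior"

REGIONS: tuple[str, ...] = ("anterior", "central", "posterior")


def montage_region(label: str) -> str | None:
    """Region of a standard 10–20 label, or None for unknown labels."""
    return _REGION_OF.get(label)


def region_assignment(channel_labels: list[str] | tuple[str, ...]) -> list[str]:
    """Assign each channel to anterior/central/posterior.

    Known 10–20 labels use the montage map; for any other label set the
    channel order is assumed anterior → posterior and split into three
    contiguous, near-equal blocks.
    """
    if all(lab in _REGION_OF for lab in channel_labels):
        return [_REGION_OF[lab] for lab in channel_labels]
    n = len(channel_labels)
    out = []
    for i in range(n):
        out.append(REGIONS[min(i * 3 // max(n, 1), 2)])
    return out
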