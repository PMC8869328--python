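"""Generate the synthetic resting-state EEG cohort and archive it.

Produces a scaled study cohort (6 subjects per group, 6 electrodes spanning
the anterior-posterior axis, 12-s segments at 64 Hz) whose band-specific
coupling and amplitude presets encode the expected group structure:
delta coupling/power strongest in MCI, alpha/beta strongest in SCI.
"""

from pathlib import Path

from epenet.pipeline import scaled_config
from epenet.synthgen import generate_cohort, write_cohort

OUT = Path("results/cohort")
SEED = 1


def main() -> None:
    cfg = scaled_config(seed=SEED)
    cohort = cfg.cohort
    segments = generate_cohort(cohort)
    write_cohort(segments, OUT)
    print(f"wrote {len(segments)} segments to {OUT}/")
    print(f"channels: {', '.join(cohort.channel_labels)}  fs={cohort.fs} Hz  "
          f"{cohort.segment_seconds} s per segment")
    print("coupling preset (group, band -> c):")
    for (g, b), c in sorted(cohort.band_coupling.items()):
        print(f"  {g:3s} {b:5s} coupling={c:.2f} amplitude={cohort.band_amplitude[(g, b)]:.2f}")


if __name__ == "__main__":
    main()
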