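#!/usr/bin/env python
"""Simulate the study's EEG corpus: one 216 s, 14-channel, 128 Hz recording
per emotion state (neutral / fear / anger) from the shipped profiles.

Writes the recordings (large CSVs) under scratch/recordings/ and a small
per-state band-power composition table under results/.
"""

from pathlib import Path

import pandas as pd

from emosafe import BANDS, band_psd, write_eeg_csv
from emosafe.experiments import make_study_recordings

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rec_dir = ROOT / "scratch" / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)

    rows = []
    for rec in make_study_recordings(seed=SEED):
        path = write_eeg_csv(rec, rec_dir / f"{rec.state_label}.csv")
        powers = {
            name: band_psd(rec.samples[rec.channel_index("T7")], rec.fs, band)
            for name, band in BANDS.items()
        }
        total = sum(powers.values())
        rows.append(
            {
                "state": rec.state_label,
                "duration_s": rec.duration,
                **{f"{b}_power_frac": p / total for b, p in powers.items()},
            }
        )
        print(f"wrote {path} ({rec.duration:.0f} s, {rec.n_channels} channels)")

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "eeg_band_composition.csv", index=False)
    print("\nT7 band-power composition by state:")
    print(table.round(3).to_string(index=False))
    print("\nEach state has a distinct dominant rhythm, which is what the")
    print("per-band classifier downstream will exploit.")


if __name__ == "__main__":
    main()
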