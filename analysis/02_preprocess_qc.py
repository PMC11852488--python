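#!/usr/bin/env python
"""Preprocessing quality control on artifact-contaminated synthetic EEG.

Injects scheduled blinks and 50 Hz mains interference into a clean
recording, runs the conditioning chain (baseline -> 0.5-50 Hz band-pass ->
notch -> 1 s epochs -> threshold rejection), and verifies that the notch
kills the mains line and that rejection flags the blink epochs.
"""

import json
from pathlib import Path

import numpy as np

from emosafe import (
    DEFAULT_PROFILES,
    bandpass_filter,
    baseline_correct,
    generate_recording,
    inject_artifacts,
    notch_filter,
    psd_spectrum,
    reject_artifact_epochs,
    segment_epochs,
)

SEED = 2
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rec = generate_recording(DEFAULT_PROFILES["fear"], duration=216, fs=128, seed=SEED)
    noisy, blink_times = inject_artifacts(
        rec, blink_rate=4.0, blink_amplitude=500.0,
        line_freq=50.0, line_amplitude=30.0, seed=SEED,
    )

    freqs, pxx_before = psd_spectrum(noisy.samples[0], rec.fs)
    conditioned = notch_filter(bandpass_filter(baseline_correct(noisy)))
    _, pxx_after = psd_spectrum(conditioned.samples[0], rec.fs)
    bin50 = int(np.argmin(np.abs(freqs - 50.0)))
    line_suppression_db = float(10 * np.log10(pxx_before[bin50] / pxx_after[bin50]))

    epochs = segment_epochs(conditioned, window_length=1.0)
    kept, rejected = reject_artifact_epochs(
        epochs, amplitude_limit=100.0, gradient_limit=200.0
    )
    blink_epochs = sorted({int(t) for t in blink_times})

    summary = {
        "injected_blinks": len(blink_times),
        "blink_epochs": blink_epochs,
        "rejected_epochs": [int(i) for i in rejected],
        "epochs_kept": kept.n_epochs,
        "line_suppression_db_at_50hz": round(line_suppression_db, 1),
    }
    out = ROOT / "results" / "preprocess_qc.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2))

    print(f"injected {len(blink_times)} blinks; rejection flagged epochs {rejected}")
    print(f"epochs containing blink onsets: {blink_epochs}")
    print(f"50 Hz line suppressed by {line_suppression_db:.1f} dB")
    print(f"{kept.n_epochs}/216 epochs retained -> results/preprocess_qc.json")


if __name__ == "__main__":
    main()
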