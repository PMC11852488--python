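"""Signal conditioning: baseline correction, band-pass, notch, epoching,
threshold-based artifact rejection.

All filtering is zero-phase (forward-backward application), so epoch
boundaries stay aligned with the raw time axis.  Band-pass filters are
Hamming-windowed sinc FIRs; the notch is a narrow IIR.  Artifact removal is
amplitude/gradient threshold rejection of whole epochs, which suffices for
synthetic data whose artifact schedule is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import EEGRecording


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch configuration.

    ``transition_width`` sets the FIR transition band (Hz) and hence the
    filter length (~3.3 * fs / width taps, Hamming window).
    """

    f_lo: float = 0.5
    f_hi: float = 50.0
    notch_freq: float = 50.0
    notch_bandwidth: float = 2.0
    transition_width: float = 1.0

    def validate(self, fs: float) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.f_hi >= fs / 2:
            raise ValueError(f"f_hi={self.f_hi} Hz must be below Nyquist ({fs / 2} Hz)")
        if self.notch_freq >= fs / 2:
            raise ValueError(
                f"notch_freq={self.notch_freq} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")


@dataclass
class EpochSet:
    """Fixed-length windows cut from one or more recordings.

    ``epochs`` has shape (n_epochs, n_channels, n_samples); ``labels`` holds
    one class label per epoch and ``source_ids`` the originating recording.
    """

    epochs: np.ndarray
    fs: float
    window_length: float
    labels: list[str | None]
    channel_labels: tuple[str, ...]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if len(self.epochs) < 1:
            raise ValueError("an EpochSet must contain at least one epoch")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels must align 1:1 with epochs")
        if not self.source_ids:
            self.source_ids = [""] * len(self.epochs)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown channel {label!r}; available: "
                f"{', '.join(self.channel_labels)}"
            ) from None


def baseline_correct(rec: EEGRecording) -> EEGRecording:
    """Remove each channel's mean (DC drift correction)."""
    if rec.n_times == 0:
        raise ValueError("cannot baseline-correct an empty recording")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=1, keepdims=True))


def _fir_taps(fs: float, transition_width: float) -> int:
    # Hamming-window design rule; forced odd for a type-I (symmetric) filter.
    n = int(np.ceil(3.3 * fs / transition_width))
    return n + 1 if n % 2 == 0 else n


def _filtfilt(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def bandpass_filter(rec: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Zero-phase Hamming-windowed sinc FIR band-pass."""
    spec.validate(rec.fs)
    numtaps = _fir_taps(rec.fs, spec.transition_width)
    taps = signal.firwin(
        numtaps,
        [spec.f_lo, spec.f_hi],
        pass_zero=False,
        window="hamming",
        width=spec.transition_width,
        fs=rec.fs,
    )
    return rec.with_samples(_filtfilt(taps, rec.samples))


def band_filter(
    rec: EEGRecording, f_lo: float, f_hi: float, transition_width: float = 1.0
) -> EEGRecording:
    """Zero-phase FIR band-pass restricted to a single analysis band."""
    return bandpass_filter(
        rec, FilterSpec(f_lo=f_lo, f_hi=f_hi, transition_width=transition_width)
    )


def notch_filter(
    rec: EEGRecording, notch_freq: float = 50.0, bandwidth: float = 2.0
) -> EEGRecording:
    """Zero-phase narrow notch (mains-interference suppression)."""
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if notch_freq >= rec.fs / 2:
        raise ValueError(
            f"notch_freq={notch_freq} Hz must be below Nyquist ({rec.fs / 2} Hz)"
        )
    b, a = signal.iirnotch(notch_freq, Q=notch_freq / bandwidth, fs=rec.fs)
    padlen = min(3 * max(len(b), len(a)), rec.n_times - 1)
    out = signal.filtfilt(b, a, rec.samples, axis=-1, padlen=padlen)
    return rec.with_samples(out)


def segment_epochs(
    rec: EEGRecording, window_length: float = 1.0, source_id: str = ""
) -> EpochSet:
    """Cut a recording into consecutive non-overlapping fixed windows.

    A trailing partial window is dropped, so every epoch has the same shape.
    Each epoch inherits the recording's state label.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    win = int(round(window_length * rec.fs))
    n_epochs = rec.n_times // win
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than the "
            f"{window_length} s window"
        )
    trimmed = rec.samples[:, : n_epochs * win]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, win).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        window_length=window_length,
        labels=[rec.state_label] * n_epochs,
        channel_labels=rec.channel_labels,
        source_ids=[source_id or rec.meta.get("profile", "")] * n_epochs,
    )


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack several epoch sets (same fs/window/channels) into one."""
    first = sets[0]
    for s in sets[1:]:
        if (s.fs, s.window_length, s.channel_labels) != (
            first.fs,
            first.window_length,
            first.channel_labels,
        ):
            raise ValueError("epoch sets are not layout-compatible")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        fs=first.fs,
        window_length=first.window_length,
        labels=[lab for s in sets for lab in s.labels],
        channel_labels=first.channel_labels,
        source_ids=[sid for s in sets for sid in s.source_ids],
    )


def reject_artifact_epochs(
    epochs: EpochSet,
    amplitude_limit: float = 100.0,
    gradient_limit: float = 200.0,
) -> tuple[EpochSet, list[int]]:
    """Drop epochs exceeding amplitude or sample-to-sample gradient limits.

    The default gradient limit is deliberately permissive: broadband
    synthetic EEG has large legitimate sample-to-sample steps, so the
    gradient check only guards against pathological jumps.

    Returns the retained epochs and the indices of rejected ones.  Raises if
    every epoch is rejected, since downstream stages need at least one.
    """
    if amplitude_limit <= 0 or gradient_limit <= 0:
        raise ValueError("rejection limits must be positive")
    amp_bad = np.abs(epochs.epochs).max(axis=(1, 2)) > amplitude_limit
    grad_bad = (
        np.abs(np.diff(epochs.epochs, axis=-1)).max(axis=(1, 2)) > gradient_limit
    )
    bad = amp_bad | grad_bad
    rejected = [int(i) for i in np.flatnonzero(bad)]
    if bad.all():
        raise ValueError(
            f"all {epochs.n_epochs} epochs rejected "
            f"(amplitude_limit={amplitude_limit}, gradient_limit={gradient_limit})"
        )
    keep = ~bad
    kept = EpochSet(
        epochs=epochs.epochs[keep],
        fs=epochs.fs,
        window_length=epochs.window_length,
        labels=[lab for lab, k in zip(epochs.labels, keep) if k],
        channel_labels=epochs.channel_labels,
        source_ids=[sid for sid, k in zip(epochs.source_ids, keep) if k],
    )
    return kept, rejected
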