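"""Core containers: multichannel EEG recordings and frequency-band definitions.

The recording layout mirrors a 14-channel consumer EEG headset sampled at
128 Hz (AF3 ... AF4, 10-20 positions), which is the acquisition geometry the
rest of the pipeline assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical 14-channel montage, in fixed order.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Emotion classes used throughout.
STATES: tuple[str, ...] = ("neutral", "fear", "anger")

DEFAULT_FS: float = 128.0


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [f_lo, f_hi) in Hz.

    The half-open convention means a band edge shared between two bands
    (e.g. 4 Hz) belongs to the upper band only, so adjacent band powers
    are additive.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r} requires 0 < f_lo < f_hi, "
                f"got [{self.f_lo}, {self.f_hi})"
            )

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies inside [f_lo, f_hi)."""
        return (freqs >= self.f_lo) & (freqs < self.f_hi)


#: Default analysis bands.  Note the deliberate 30-31 Hz gap between beta
#: and gamma: the convention partitions rhythms as delta 1-4, theta 4-8,
#: alpha 8-13, beta 13-30 and gamma 31-47 Hz, and the gap is preserved
#: rather than silently closed.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 47.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)


def get_band(name: str) -> BandDefinition:
    try:
        return BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; known bands: {', '.join(BANDS)}"
        ) from None


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per row of ``samples``.
    state_label : str or None
        Emotion class of the recording, if known.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: tuple[str, ...] = CHANNELS
    state_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels were given"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_times / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown channel {label!r}; available: "
                f"{', '.join(self.channel_labels)}"
            ) from None

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``samples`` replaced."""
        return replace(self, samples=np.asarray(samples, dtype=float))
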