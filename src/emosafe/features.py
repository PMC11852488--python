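"""Per-epoch features: sample entropy and band power spectral density.

Sample entropy (SampEn) follows the Richman-Moorman estimator: with
embedding dimension ``m`` and tolerance ``r``, count pairs of length-``m``
templates (B) and length-``m+1`` templates (A) whose Chebyshev distance is
at most ``r``, over the first ``N - m`` templates for both lengths, each
unordered pair counted once and self-matches excluded; SampEn = -ln(A / B).
It is a finite-sample estimate of the conditional probability that two
sequences that match for m points keep matching for m + 1.

Band PSD is the raw (boxcar, untapered) periodogram |X(f)|^2 / T integrated
over a half-open frequency band, i.e. the signal power attributable to that
band in squared input units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist

from .preprocess import EpochSet
from .recording import BandDefinition


class UndefinedEntropyError(ValueError):
    """Raised when SampEn is undefined because no template pairs match."""


@dataclass(frozen=True)
class SampEnParams:
    """SampEn configuration.

    ``r`` is a fraction of the series' (population) standard deviation
    unless ``r_absolute`` is set, in which case it is an absolute tolerance
    in signal units.  Defaults m=2, r=0.2*SD are the standard choice for
    short physiological series.
    """

    m: int = 2
    r: float = 0.2
    r_absolute: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance r must be positive, got {self.r}")


def sample_entropy(series, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy -ln(A/B) of a 1-D series.

    Returns 0.0 for a constant series (every template matches every other,
    so A = B).  Raises :class:`UndefinedEntropyError` when no m-length or no
    (m+1)-length template pair matches within tolerance.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    m = params.m
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m + 1 = {m + 1}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    if params.r_absolute:
        r = params.r
    else:
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0
        r = params.r * sd

    n_templates = n - m

    def pair_matches(order: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, order)[:n_templates]
        return int(np.count_nonzero(pdist(emb, metric="chebyshev") <= r))

    b = pair_matches(m)
    if b == 0:
        raise UndefinedEntropyError(
            f"no length-{m} template pairs match within r={r:g}; SampEn undefined"
        )
    a = pair_matches(m + 1)
    if a == 0:
        raise UndefinedEntropyError(
            f"no length-{m + 1} template pairs match within r={r:g}; "
            "SampEn undefined (infinite)"
        )
    return float(-np.log(a / b))


def psd_spectrum(series, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided raw periodogram (freqs in Hz, density in power/Hz).

    Untapered and undetrended, so the Parseval identity
    ``sum(psd) * df == mean(x**2)`` holds exactly.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("series must contain at least 2 samples")
    freqs, pxx = signal.periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    return freqs, pxx


def band_psd(series, fs: float, band: BandDefinition) -> float:
    """Signal power in ``band`` (periodogram integrated over [f_lo, f_hi))."""
    if band.f_hi > fs / 2:
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}) Hz exceeds the "
            f"Nyquist frequency {fs / 2} Hz"
        )
    freqs, pxx = psd_spectrum(series, fs)
    mask = band.contains(freqs)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}) Hz contains no "
            f"frequency bins at fs={fs} Hz with {len(series)} samples"
        )
    df = freqs[1] - freqs[0]
    return float(pxx[mask].sum() * df)


@dataclass
class FeatureMatrix:
    """Per-epoch feature rows for one analysis band.

    Columns are ``sampen_<ch>`` for each selected channel followed by
    ``psd_<band>_<ch>``; the order is fixed and recorded in ``columns``.
    """

    values: np.ndarray
    columns: list[str]
    labels: list[str | None]
    band: BandDefinition
    channels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (epochs x features)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names must match the feature count")
        if len(self.labels) != len(self.values):
            raise ValueError("labels must align 1:1 with feature rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return len(self.values)


def build_feature_matrix(
    epochs: EpochSet,
    channels: tuple[str, ...] = ("T7", "T8"),
    band: BandDefinition | None = None,
    sampen: SampEnParams = SampEnParams(),
) -> FeatureMatrix:
    """Assemble (SampEn, band-PSD) features per epoch on selected channels.

    SampEn is computed on the epoch samples exactly as provided — callers
    that want band-specific complexity band-filter the recording before
    epoching.  Band PSD is the power of the same samples inside ``band``.
    """
    if band is None:
        raise ValueError("a BandDefinition is required")
    if not channels:
        raise ValueError("at least one channel must be selected")
    ch_idx = [epochs.channel_index(ch) for ch in channels]

    n = epochs.n_epochs
    values = np.empty((n, 2 * len(channels)))
    for i in range(n):
        for j, ci in enumerate(ch_idx):
            series = epochs.epochs[i, ci]
            values[i, j] = sample_entropy(series, sampen)
            values[i, len(channels) + j] = band_psd(series, epochs.fs, band)

    columns = [f"sampen_{ch}" for ch in channels] + [
        f"psd_{band.name}_{ch}" for ch in channels
    ]
    return FeatureMatrix(
        values=values,
        columns=columns,
        labels=list(epochs.labels),
        band=band,
        channels=tuple(channels),
    )
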