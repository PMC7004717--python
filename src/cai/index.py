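"""The cortical activity index (CAI).

CAI rests on a simple time-domain picture of anesthesia: awake cortex
produces many brief, low-amplitude "peak" deflections, while deepening
anesthesia replaces them with large slow waves and, eventually, long
near-isoelectric stretches.  Per analysis epoch the index is the
*density of peak samples* — the fraction of samples whose rectified
amplitude exceeds an adaptive threshold.

The threshold must adapt because EEG amplitude grows severalfold from
awake to deep anesthesia.  It is derived from the low-frequency content
of the same epoch::

    T = K * (1/M) * sum_{k=1..M} |DFT(x)[k]| / N

with ``N`` the epoch length in samples, ``M`` the number of
low-frequency DFT bins averaged (DC excluded) and ``K`` a dimensionless
gain.  Slow-wave-dominated (deep) epochs therefore receive a high
threshold and score a low density; low-amplitude broadband (awake)
epochs receive a low threshold and score high.  The density stream is
smoothed with a centered moving average and mapped to a 0-100 display
scale.

Defaults: 4 s epochs advancing every 2 s at 128 Hz (N=512, step=256),
``M=16`` so the average covers 0.25-4 Hz (the delta band, the
canonical deep-anesthesia signature), ``K=6``, 15-epoch (~30 s)
smoothing.  ``K`` and ``M`` are deliberately configuration values —
calibration constants, not universal: the defaults are calibrated on
the synthetic simulator so that awake recordings score above ~70 and
deep burst-suppression recordings below ~30 on the display scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecord, IndexSeries, ValidationError

__all__ = [
    "EpochingParams",
    "ThresholdParams",
    "CaiParams",
    "Epoch",
    "segment_epochs",
    "low_freq_magnitude",
    "adaptive_threshold",
    "peak_density",
    "compute_cai",
]


@dataclass(frozen=True)
class EpochingParams:
    """Epoch geometry in samples: window length and hop."""

    epoch_len: int = 256
    step: int = 256

    def __post_init__(self) -> None:
        if self.epoch_len < 4:
            raise ValidationError(f"epoch_len must be >= 4, got {self.epoch_len}")
        if not 1 <= self.step <= self.epoch_len:
            raise ValidationError(
                f"step must satisfy 1 <= step <= epoch_len, got {self.step}"
            )


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive-threshold constants: gain ``K`` and low-frequency bin count ``M``."""

    K: float = 6.0
    M: int = 16

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValidationError(f"K must be positive, got {self.K}")
        if self.M < 1:
            raise ValidationError(f"M must be >= 1, got {self.M}")


@dataclass(frozen=True)
class Epoch:
    """One analysis window: samples in microvolts plus its center time."""

    samples: np.ndarray
    t_center: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ValidationError("Epoch samples must be finite")


@dataclass(frozen=True)
class CaiParams:
    """Full CAI pipeline configuration."""

    epoching: EpochingParams = field(
        default_factory=lambda: EpochingParams(epoch_len=512, step=256)
    )
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    #: centered moving-average width, in epochs (~30 s at the defaults)
    smooth_epochs: int = 15
    #: linear gain from raw density in [0,1] to the display scale
    display_gain: float = 100.0

    def __post_init__(self) -> None:
        if self.smooth_epochs < 1:
            raise ValidationError("smooth_epochs must be >= 1")
        if not self.display_gain > 0:
            raise ValidationError("display_gain must be positive")
        if not self.threshold.M < self.epoching.epoch_len / 2:
            raise ValidationError(
                f"M={self.threshold.M} must be < epoch_len/2="
                f"{self.epoching.epoch_len / 2}"
            )


def segment_epochs(record: EEGRecord, params: EpochingParams) -> list[Epoch]:
    """Tile a record into fixed-length epochs.

    Windows start every ``step`` samples; a trailing partial window is
    discarded.  Epoch center times are
    ``t0 + (start + epoch_len/2) / fs`` seconds.
    """
    starts, mat = _epoch_matrix(record, params)
    t_center = record.t0 + (starts + params.epoch_len / 2) / record.fs
    return [Epoch(row, float(t)) for row, t in zip(mat, t_center)]


def _epoch_matrix(
    record: EEGRecord, params: EpochingParams
) -> tuple[np.ndarray, np.ndarray]:
    n, L, s = record.n_samples, params.epoch_len, params.step
    if n < L:
        raise ValidationError(
            f"record of {n} samples is shorter than one epoch ({L} samples)"
        )
    starts = np.arange(0, n - L + 1, s)
    idx = starts[:, None] + np.arange(L)[None, :]
    return starts, record.samples[idx]


def low_freq_magnitude(epoch: Epoch | np.ndarray, M: int) -> float:
    """Mean DFT magnitude over the first ``M`` non-DC bins.

    Returns ``(1/M) * sum_{k=1..M} |DFT(x)[k]|`` in microvolt-sample
    units; bin 0 (DC) is excluded, so the result is invariant to a
    constant offset.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    N = x.size
    if not 1 <= M < N / 2:
        raise ValidationError(f"M must satisfy 1 <= M < epoch_len/2; got M={M}, N={N}")
    spectrum = np.fft.rfft(x)
    return float(np.mean(np.abs(spectrum[1 : M + 1])))


def adaptive_threshold(epoch: Epoch | np.ndarray, params: ThresholdParams) -> float:
    """Per-epoch amplitude threshold ``K * low_freq_magnitude / N`` in microvolts.

    Dividing by the epoch length converts DFT magnitude back to the
    amplitude scale (an on-bin cosine of amplitude ``A`` has
    ``|DFT| = A*N/2``).  The threshold is positively homogeneous —
    ``T(c*x) = c*T(x)`` for ``c > 0`` — and ignores DC offset, so it
    tracks the signal's own low-frequency amplitude: low for awake
    low-voltage EEG, high for slow-wave-dominated deep EEG.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    return params.K * low_freq_magnitude(x, params.M) / x.size


def peak_density(epoch: Epoch | np.ndarray, threshold: float) -> float:
    """Fraction of epoch samples whose rectified amplitude exceeds ``threshold``.

    The comparison is strict (``|x| > T``) on the rectified signal;
    the result lies in [0, 1] and is non-increasing in the threshold.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    return float(np.count_nonzero(np.abs(x) > threshold)) / x.size


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with a window that shrinks at the edges.

    NaN entries are excluded from the average (and stay NaN where the
    whole window is NaN).  ``width=1`` is the identity.
    """
    v = np.asarray(values, dtype=float)
    if width < 1:
        raise ValidationError("smoothing width must be >= 1")
    if width == 1 or v.size == 0:
        return v.copy()
    ok = np.isfinite(v)
    kernel = np.ones(width)
    # slice the full convolution: mode="same" would misbehave for
    # windows wider than the series
    lo = (width - 1) // 2
    num = np.convolve(np.where(ok, v, 0.0), kernel, mode="full")[lo : lo + v.size]
    den = np.convolve(ok.astype(float), kernel, mode="full")[lo : lo + v.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def compute_cai(record: EEGRecord, params: CaiParams | None = None) -> IndexSeries:
    """Compute the CAI stream for a record.

    Per epoch: adaptive threshold -> peak density; then a centered
    moving average over ``smooth_epochs`` epochs and a linear map to
    the 0-100 display scale (clipped).  One value per epoch step,
    timestamped at the epoch center.  Deterministic: identical input
    yields identical output.
    """
    params = params or CaiParams()
    starts, mat = _epoch_matrix(record, params.epoching)
    N = params.epoching.epoch_len

    spectra = np.abs(np.fft.rfft(mat, axis=1))
    thresholds = (
        params.threshold.K
        * spectra[:, 1 : params.threshold.M + 1].mean(axis=1)
        / N
    )
    density = np.count_nonzero(np.abs(mat) > thresholds[:, None], axis=1) / N

    smoothed = moving_average(density, params.smooth_epochs)
    display = np.clip(params.display_gain * smoothed, 0.0, 100.0)
    t_center = record.t0 + (starts + N / 2) / record.fs
    return IndexSeries("CAI", t_center, display)
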