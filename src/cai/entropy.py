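"""Reference spectral-entropy (SpEn) index.

Spectral entropy quantifies the irregularity of the EEG power
spectrum: Shannon entropy of the spectrum normalized to a probability
distribution, divided by ``log(nbins)`` so a flat (broadband, awake)
spectrum scores 1 and a single-line (slow, deep) spectrum scores 0.
This is the state-entropy-style construction over a fixed EEG band —
here 0.8-32 Hz with no electromyogram band — scaled to 0-100 and
smoothed exactly like CAI so the two streams are directly comparable.

Epochs default to 8 s (1024 samples at 128 Hz) advancing every 2 s:
the 0.8 Hz band floor needs a frequency resolution finer than the
0.5 Hz a 2 s window can give, and long windows stabilize the entropy
of broadband segments.  The periodogram is rectangular-windowed
(unwindowed), so tones off the DFT grid leak across neighboring bins
and score a small but non-zero entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .index import Epoch, EpochingParams, _epoch_matrix, moving_average
from .io import EEGRecord, IndexSeries, ValidationError

__all__ = [
    "SpenParams",
    "band_power_spectrum",
    "spectral_entropy",
    "compute_spen",
]


@dataclass(frozen=True)
class SpenParams:
    """Spectral-entropy configuration: band, epoching, smoothing."""

    band: tuple[float, float] = (0.8, 32.0)
    epoching: EpochingParams = field(
        default_factory=lambda: EpochingParams(epoch_len=1024, step=256)
    )
    smooth_epochs: int = 15

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise ValidationError(f"band must satisfy 0 <= lo < hi, got {self.band}")
        if self.smooth_epochs < 1:
            raise ValidationError("smooth_epochs must be >= 1")


def band_power_spectrum(
    epoch: Epoch | np.ndarray, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """One-sided periodogram powers restricted to a frequency band.

    Returns ``c_k * |DFT(x)[k]|**2`` for the bins whose frequency lies
    in ``[band[0], band[1]]``, with ``c_k = 2`` for interior bins and 1
    for DC/Nyquist, so that over the full band the powers sum to
    ``N * sum(x**2)`` (Parseval).
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    N = x.size
    lo, hi = band
    if hi > fs / 2 + 1e-12:
        raise ValidationError(f"band {band} exceeds Nyquist frequency {fs / 2}")
    freqs = np.fft.rfftfreq(N, d=1.0 / fs)
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not np.any(mask):
        raise ValidationError(
            f"band {band} contains no DFT bins at fs={fs}, epoch_len={N}"
        )
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if N % 2 == 0:
        weights[-1] = 1.0
    return (weights * spectrum)[mask]


def spectral_entropy(powers: np.ndarray) -> float:
    """Normalized Shannon entropy of a power spectrum, in [0, 1].

    ``H = -sum(p_i log p_i) / log(nbins)`` with ``p_i = P_i / sum(P)``.
    1 for a flat spectrum, 0 when all power sits in one bin.  Scale-
    and permutation-invariant; base-independent after normalization.
    """
    P = np.asarray(powers, dtype=float)
    if P.size < 2:
        raise ValidationError(f"need >= 2 spectral bins, got {P.size}")
    if np.any(P < 0):
        raise ValidationError("spectral powers must be non-negative")
    total = P.sum()
    if total <= 0:
        raise ValidationError("total spectral power is zero; entropy undefined")
    p = P / total
    nz = p > 0
    H = -float(np.sum(p[nz] * np.log(p[nz])))
    return H / np.log(P.size)


def compute_spen(record: EEGRecord, params: SpenParams | None = None) -> IndexSeries:
    """Compute the SpEn stream (0-100) for a record.

    Per epoch: band-restricted periodogram -> normalized entropy x 100;
    epochs with zero in-band power are treated as missing and excluded
    from the moving-average smoothing.  If every epoch is missing an
    empty series is returned with a warning.
    """
    params = params or SpenParams()
    if record.fs / 2 < params.band[1]:
        raise ValidationError(
            f"record fs={record.fs} cannot support band {params.band}"
        )
    starts, mat = _epoch_matrix(record, params.epoching)
    N = params.epoching.epoch_len

    freqs = np.fft.rfftfreq(N, d=1.0 / record.fs)
    lo, hi = params.band
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValidationError(
            f"band {params.band} yields fewer than 2 bins at fs={record.fs}"
        )
    P = np.abs(np.fft.rfft(mat, axis=1)[:, mask]) ** 2
    totals = P.sum(axis=1)

    entropies = np.full(mat.shape[0], np.nan)
    ok = totals > 0
    if np.any(ok):
        p = P[ok] / totals[ok, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropies[ok] = -plogp.sum(axis=1) / np.log(int(mask.sum()))

    t_center = record.t0 + (starts + N / 2) / record.fs
    if not np.any(ok):
        warnings.warn(
            "all epochs have zero in-band power; SpEn series is empty",
            stacklevel=2,
        )
        return IndexSeries("SpEn", np.empty(0), np.empty(0))

    smoothed = moving_average(entropies, params.smooth_epochs)
    keep = np.isfinite(smoothed)
    values = np.clip(100.0 * smoothed[keep], 0.0, 100.0)
    return IndexSeries("SpEn", t_center[keep], values)
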