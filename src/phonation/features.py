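"""Perturbation and harmonicity features of a voiced segment.

Twelve classifier features per phoneme: four jitter variants (abs, rel,
rap, ppq5) on the period sequence T_i, five shimmer variants (dB, rel,
apq3, apq5, apq11) on the amplitude sequence A_i, the standard deviation
of the instantaneous pitch f0_i = 1/T_i, and the harmonicity pair
HNR/NHR from the normalized autocorrelation peak r(T0):

    HNR = 10 log10( r / (1 - r) )        NHR = 1 - r

The mean, median, max and min pitch are computed as well but kept out of
the classifier block (they carry strong speaker/sex information).

All ratio features are dimensionless fractions; jitter(abs) is in
seconds, shimmer(dB) and HNR in decibels.  A feature whose minimum period
count is not met is returned as NaN ("missing").
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np

from .core import InsufficientPeriodsError, PulseSequence, UnvoicedSegmentError

__all__ = [
    "CLASSIFIER_FEATURES",
    "EXCLUDED_PITCH_FEATURES",
    "JitterFeatures",
    "ShimmerFeatures",
    "PitchStatistics",
    "Harmonicity",
    "jitter_features",
    "shimmer_features",
    "pitch_statistics",
    "harmonicity",
    "segment_features",
]

#: Per-phoneme classifier feature names, in fixed column order.
CLASSIFIER_FEATURES = [
    "jit_abs",
    "jit_rel",
    "jit_rap",
    "jit_ppq5",
    "shim_db",
    "shim_rel",
    "shim_apq3",
    "shim_apq5",
    "shim_apq11",
    "pitch_std",
    "hnr",
    "nhr",
]

#: Pitch statistics excluded from classification (kept for the tables).
EXCLUDED_PITCH_FEATURES = ["pitch_mean", "pitch_median", "pitch_max", "pitch_min"]

DEFAULT_HNR_CEILING_DB = 40.0


class JitterFeatures(NamedTuple):
    jit_abs: float
    jit_rel: float
    jit_rap: float
    jit_ppq5: float


class ShimmerFeatures(NamedTuple):
    shim_db: float
    shim_rel: float
    shim_apq3: float
    shim_apq5: float
    shim_apq11: float


class PitchStatistics(NamedTuple):
    pitch_mean: float
    pitch_median: float
    pitch_std: float
    pitch_max: float
    pitch_min: float


class Harmonicity(NamedTuple):
    hnr: float
    nhr: float


def _mean_abs_dev_from_moving_mean(x: np.ndarray, window: int) -> float:
    """Mean |x_i - centered moving mean| over all full windows, NaN if the
    sequence is shorter than the window."""
    n = len(x)
    if n < window:
        return math.nan
    half = window // 2
    kernel = np.ones(window) / window
    mov = np.convolve(x, kernel, mode="valid")  # length n - window + 1
    centers = x[half : n - half]
    return float(np.mean(np.abs(centers - mov)))


def jitter_features(pulses: PulseSequence) -> JitterFeatures:
    """Cycle-to-cycle period perturbation (abs, rel, rap, ppq5)."""
    T = pulses.T
    n = len(T)
    if n < 2:
        raise InsufficientPeriodsError("jitter needs at least 2 periods")
    mean_t = float(np.mean(T))
    jit_abs = float(np.mean(np.abs(np.diff(T))))
    jit_rel = jit_abs / mean_t
    jit_rap = _mean_abs_dev_from_moving_mean(T, 3) / mean_t
    jit_ppq5 = _mean_abs_dev_from_moving_mean(T, 5) / mean_t
    return JitterFeatures(jit_abs, jit_rel, jit_rap, jit_ppq5)


def shimmer_features(pulses: PulseSequence) -> ShimmerFeatures:
    """Cycle-to-cycle amplitude perturbation (dB, rel, apq3, apq5, apq11).

    The dB variant averages |20 log10(A_{i+1}/A_i)| per cycle pair.
    """
    A = pulses.A
    n = len(A)
    if n < 2:
        raise InsufficientPeriodsError("shimmer needs at least 2 periods")
    mean_a = float(np.mean(A))
    shim_db = float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1]))))
    shim_rel = float(np.mean(np.abs(np.diff(A)))) / mean_a
    apq3 = _mean_abs_dev_from_moving_mean(A, 3) / mean_a
    apq5 = _mean_abs_dev_from_moving_mean(A, 5) / mean_a
    apq11 = _mean_abs_dev_from_moving_mean(A, 11) / mean_a
    return ShimmerFeatures(shim_db, shim_rel, apq3, apq5, apq11)


def pitch_statistics(pulses: PulseSequence) -> PitchStatistics:
    """Mean / median / sample std / max / min of f0_i = 1/T_i (Hz)."""
    T = pulses.T
    if len(T) < 2:
        raise InsufficientPeriodsError("pitch statistics need at least 2 periods")
    f0 = 1.0 / T
    return PitchStatistics(
        pitch_mean=float(np.mean(f0)),
        pitch_median=float(np.median(f0)),
        pitch_std=float(np.std(f0, ddof=1)),
        pitch_max=float(np.max(f0)),
        pitch_min=float(np.min(f0)),
    )


def harmonicity(r_t0: float, ceiling_db: float = DEFAULT_HNR_CEILING_DB) -> Harmonicity:
    """HNR (dB) and NHR from the normalized autocorrelation pitch peak.

    ``r_t0 <= 0`` means no harmonic energy: the segment is reported
    unvoiced.  ``r_t0 >= 1`` (possible with unbiased normalization on
    perfectly periodic input) caps HNR at ``ceiling_db`` with a warning.
    """
    if r_t0 <= 0.0:
        raise UnvoicedSegmentError(f"autocorrelation peak {r_t0:.3f} is not positive")
    if r_t0 >= 1.0:
        warnings.warn(
            f"autocorrelation peak {r_t0:.6f} >= 1; HNR capped at {ceiling_db} dB",
            stacklevel=2,
        )
        return Harmonicity(hnr=ceiling_db, nhr=max(1.0 - r_t0, 0.0))
    hnr = 10.0 * math.log10(r_t0 / (1.0 - r_t0))
    return Harmonicity(hnr=min(hnr, ceiling_db), nhr=1.0 - r_t0)


def segment_features(
    pulses: PulseSequence, r_t0: float, hnr_ceiling_db: float = DEFAULT_HNR_CEILING_DB
) -> dict[str, float]:
    """All 12 classifier features plus the excluded pitch block, by name."""
    jit = jitter_features(pulses)
    shim = shimmer_features(pulses)
    pitch = pitch_statistics(pulses)
    harm = harmonicity(r_t0, ceiling_db=hnr_ceiling_db)
    out = {
        **jit._asdict(),
        **shim._asdict(),
        "pitch_std": pitch.pitch_std,
        **harm._asdict(),
        "pitch_mean": pitch.pitch_mean,
        "pitch_median": pitch.pitch_median,
        "pitch_max": pitch.pitch_max,
        "pitch_min": pitch.pitch_min,
    }
    return out
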