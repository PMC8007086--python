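"""Core containers for phonation analysis.

A sustained phonation is modelled as a quasi-periodic train of glottal
pulses.  The pulse instants ``t_i`` define the instantaneous periods
``T_i = t_{i+1} - t_i`` and per-period peak amplitudes ``A_i``; every
perturbation feature downstream is a function of these two sequences,
plus the normalized autocorrelation of the raw segment for harmonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PhonationError(Exception):
    """Base class for all package errors."""


class UnvoicedSegmentError(PhonationError):
    """No periodicity peak above the voicing threshold."""


class TooShortError(PhonationError):
    """Segment too short for the requested analysis."""


class NoPitchPeakError(PhonationError):
    """Autocorrelation has no local maximum in the pitch-lag window."""


class InsufficientPeriodsError(PhonationError):
    """Fewer periods than the feature's minimum."""


class NoVoicedRegionError(PhonationError):
    """Energy trimming found nothing above threshold."""


class RecordingTooShortError(PhonationError):
    """Trimmed recording shorter than the segmentation protocol needs."""


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    def slice_seconds(self, start: float, stop: float) -> "Waveform":
        """Half-open time window [start, stop) as a new waveform."""
        i0 = int(round(start * self.sample_rate))
        i1 = int(round(stop * self.sample_rate))
        return Waveform(self.samples[i0:i1], self.sample_rate)


@dataclass(frozen=True)
class PulseSequence:
    """Glottal pulse instants with derived periods and peak amplitudes.

    ``t`` holds N+1 pulse instants in seconds from segment start (0-based
    sample convention); ``T`` the N periods ``t[i+1]-t[i]``; ``A`` the N
    per-period peak absolute amplitudes.
    """

    t: np.ndarray
    A: np.ndarray
    T: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        A = np.asarray(self.A, dtype=np.float64)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least 2 pulse instants")
        T = np.diff(t)
        if np.any(T <= 0):
            raise ValueError("pulse instants must be strictly increasing")
        if len(A) != len(T):
            raise ValueError("need one amplitude per period")
        if np.any(A <= 0):
            raise ValueError("amplitudes must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "T", T)

    @classmethod
    def from_periods(cls, T, A=None, t0: float = 0.0) -> "PulseSequence":
        """Build from explicit periods (amplitudes default to 1)."""
        T = np.asarray(T, dtype=np.float64)
        if A is None:
            A = np.ones_like(T)
        t = t0 + np.concatenate([[0.0], np.cumsum(T)])
        return cls(t=t, A=np.asarray(A, dtype=np.float64))

    @property
    def n_periods(self) -> int:
        return len(self.T)


@dataclass(frozen=True)
class AutocorrProfile:
    """Normalized autocorrelation with the selected pitch peak.

    ``r[0] == 1``; ``t0_lag`` is the integer lag (samples) of the highest
    local maximum inside the pitch window and ``r_t0`` the (optionally
    parabolically interpolated) autocorrelation value there.
    """

    r: np.ndarray
    t0_lag: int
    r_t0: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=np.float64)
        if abs(r[0] - 1.0) > 1e-12:
            raise ValueError("autocorrelation must be normalized to r[0]=1")
        if not 0 < self.t0_lag < len(r):
            raise ValueError("t0_lag outside profile")
        object.__setattr__(self, "r", r)
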