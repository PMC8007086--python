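"""Synthetic sustained-phoneme generation with known ground truth.

The source model is a train of smooth Rosenberg-type glottal pulses.
Cycle ``i`` has period ``T_i = (1/f0) * (1 + eps_i)`` with ``eps_i`` i.i.d.
zero-mean Gaussian of std ``jitter_sigma``, and peak amplitude
``A_i = A0 * (1 + delta_i)`` with ``delta_i`` Gaussian of std
``shimmer_sigma`` (both deviations clamped at 6 sigma so periods and
amplitudes stay positive).  Pulses are rendered at continuous (sub-sample)
instants, so the returned :class:`~phonation.core.PulseSequence` is the
exact generative ground truth, not a quantized copy.

Vowel/nasal identity is imposed afterwards by a cascade of two-pole
resonators (formants) plus an optional extra spectral tilt, and breathiness
is controlled by additive Gaussian aspiration noise at a prescribed
signal-to-noise ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .core import PulseSequence, Waveform

__all__ = [
    "SynthesisParams",
    "PhonemeProfile",
    "PHONEME_PROFILES",
    "CohortConfig",
    "GroupDistribution",
    "CohortRecording",
    "synthesize_pulse_train",
    "apply_vocal_tract",
    "add_aspiration_noise",
    "synthesize_phoneme",
    "synthesize_cohort",
    "cohort_manifest",
    "synthesize_null_features",
]

# Rosenberg pulse timing as fractions of the *nominal* period 1/f0: the
# opening (rise) phase lasts 0.40/f0 and the closing (fall) phase 0.16/f0.
# Keeping the shape width tied to the nominal period (not the per-cycle
# jittered one) puts the waveform peak of cycle i exactly at t_i with
# height exactly A_i, and leaves >40% of the cycle silent so neighbouring
# pulses never overlap for any admissible jitter.
_RISE_FRAC = 0.40
_FALL_FRAC = 0.16


@dataclass(frozen=True)
class SynthesisParams:
    """Generative parameters for one sustained-phoneme recording."""

    f0: float
    duration: float
    sample_rate: float = 48000.0
    jitter_sigma: float = 0.0
    shimmer_sigma: float = 0.0
    noise_snr_db: float = math.inf
    phoneme: str = "a"
    seed: int = 0
    amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not 50.0 <= self.f0 <= 500.0:
            raise ValueError(f"f0={self.f0} outside [50, 500] Hz")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.jitter_sigma < 0 or self.shimmer_sigma < 0:
            raise ValueError("perturbation sigmas must be non-negative")
        # 6-sigma clamp must still leave periods/amplitudes positive
        if 6.0 * self.jitter_sigma >= 1.0:
            raise ValueError("jitter_sigma too large: period could hit zero at 6 sigma")
        if 6.0 * self.shimmer_sigma >= 1.0:
            raise ValueError("shimmer_sigma too large: amplitude could hit zero at 6 sigma")
        if self.phoneme not in ("a", "o", "m"):
            raise ValueError("phoneme must be one of 'a', 'o', 'm'")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class PhonemeProfile:
    """Vocal-tract colouring: formant resonances plus extra spectral tilt.

    ``formants`` is a sequence of (center frequency Hz, bandwidth Hz)
    pairs with strictly increasing centers; ``tilt_db_per_octave`` adds
    low-pass tilt on top of the resonances (negative = darker), realized
    as a cascade of one-pole low-pass sections referenced at 500 Hz.
    """

    phoneme: str
    formants: tuple[tuple[float, float], ...] = ()
    tilt_db_per_octave: float = 0.0

    def __post_init__(self) -> None:
        freqs = [f for f, _ in self.formants]
        if any(b <= 0 for _, b in self.formants):
            raise ValueError("formant bandwidths must be positive")
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("formant frequencies must be strictly increasing")


#: Textbook formant targets for the three study phonemes: the open vowel
#: /a/, the closed-mid-back vowel /o/, and the nasal /m/ (single low
#: resonance with a strongly tilted spectrum).
PHONEME_PROFILES: dict[str, PhonemeProfile] = {
    "a": PhonemeProfile("a", formants=((800.0, 80.0), (1200.0, 120.0))),
    "o": PhonemeProfile("o", formants=((450.0, 60.0), (900.0, 90.0))),
    "m": PhonemeProfile("m", formants=((250.0, 50.0),), tilt_db_per_octave=-12.0),
}


def _rosenberg(tau: np.ndarray, t_rise: float, t_fall: float) -> np.ndarray:
    """Rosenberg glottal pulse, peak 1 at tau=0, support [-t_rise, t_fall]."""
    out = np.zeros_like(tau)
    rise = (tau >= -t_rise) & (tau < 0)
    fall = (tau >= 0) & (tau <= t_fall)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * (tau[rise] + t_rise) / t_rise))
    out[fall] = np.cos(np.pi * tau[fall] / (2.0 * t_fall))
    return out


def synthesize_pulse_train(params: SynthesisParams) -> tuple[Waveform, PulseSequence]:
    """Render a jittered/shimmered glottal pulse train.

    Returns the waveform together with the exact ground-truth pulse
    sequence used to render it.  Reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    sr = params.sample_rate
    nominal = 1.0 / params.f0
    t_rise = _RISE_FRAC * nominal
    t_fall = _FALL_FRAC * nominal

    n_cycles = int(math.ceil(params.duration * params.f0)) + 2
    eps = np.clip(
        rng.normal(0.0, params.jitter_sigma, n_cycles) if params.jitter_sigma > 0 else np.zeros(n_cycles),
        -6.0 * params.jitter_sigma,
        6.0 * params.jitter_sigma,
    )
    delta = np.clip(
        rng.normal(0.0, params.shimmer_sigma, n_cycles) if params.shimmer_sigma > 0 else np.zeros(n_cycles),
        -6.0 * params.shimmer_sigma,
        6.0 * params.shimmer_sigma,
    )
    periods = nominal * (1.0 + eps)
    amps = params.amplitude * (1.0 + delta)

    # pulse peak instants: first peak after the rise phase fits in-signal
    t = t_rise + np.concatenate([[0.0], np.cumsum(periods)])
    keep = t + t_fall <= params.duration
    t = t[keep]
    amps = amps[: len(t)]
    if len(t) < 2:
        raise ValueError("duration too short for two pulses at this f0")

    n_samples = int(round(params.duration * sr))
    wave = np.zeros(n_samples)
    grid = np.arange(n_samples) / sr
    half_rise = int(math.ceil(t_rise * sr)) + 1
    half_fall = int(math.ceil(t_fall * sr)) + 1
    for ti, ai in zip(t, amps):
        center = int(round(ti * sr))
        lo = max(center - half_rise, 0)
        hi = min(center + half_fall + 1, n_samples)
        wave[lo:hi] += ai * _rosenberg(grid[lo:hi] - ti, t_rise, t_fall)

    pulses = PulseSequence(t=t, A=amps[: len(t) - 1])
    return Waveform(wave, sr), pulses


def apply_vocal_tract(wave: Waveform, profile: PhonemeProfile) -> Waveform:
    """Filter a source waveform through cascaded formant resonators.

    Linear and time-invariant; output length equals input length.  Each
    resonator is a two-pole section gain-normalized to unity at its
    center frequency; the tilt parameter adds one-pole low-pass sections
    (one per -6 dB/octave) referenced at 500 Hz.
    """
    sr = wave.sample_rate
    nyquist = sr / 2.0
    x = wave.samples
    for fc, bw in profile.formants:
        if fc >= nyquist:
            raise ValueError(f"resonance {fc} Hz at or above Nyquist {nyquist} Hz")
        r = math.exp(-math.pi * bw / sr)
        theta = 2.0 * math.pi * fc / sr
        # pole angle chosen so the magnitude response peaks exactly at fc
        # (a pole at angle theta peaks slightly below theta otherwise)
        cos_psi = (2.0 * r) / (1.0 + r * r) * math.cos(theta)
        psi = math.acos(min(max(cos_psi, -1.0), 1.0))
        a = [1.0, -2.0 * r * math.cos(psi), r * r]
        # unity gain at fc
        _, h = sps.freqz([1.0], a, worN=[theta], fs=2.0 * math.pi)
        b0 = 1.0 / abs(h[0])
        x = sps.lfilter([b0], a, x)
    n_sections = int(round(-profile.tilt_db_per_octave / 6.0))
    if n_sections > 0:
        fc_ref = 500.0
        alpha = math.exp(-2.0 * math.pi * fc_ref / sr)
        for _ in range(n_sections):
            x = sps.lfilter([1.0 - alpha], [1.0, -alpha], x)
    return Waveform(x, sr)


def add_aspiration_noise(wave: Waveform, noise_snr_db: float, seed: int) -> Waveform:
    """Add white Gaussian noise at the given signal-to-noise ratio (dB).

    ``noise_snr_db = +inf`` returns the input unchanged.
    """
    if math.isinf(noise_snr_db) and noise_snr_db > 0:
        return wave
    rng = np.random.default_rng(seed)
    p_signal = float(np.mean(wave.samples**2))
    p_noise = p_signal / 10.0 ** (noise_snr_db / 10.0)
    noise = rng.standard_normal(len(wave)) * math.sqrt(p_noise)
    return Waveform(wave.samples + noise, wave.sample_rate)


def synthesize_phoneme(params: SynthesisParams) -> tuple[Waveform, PulseSequence]:
    """Full single-recording synthesis: source, vocal tract, noise.

    The filtered waveform is rescaled to a 0.5 peak before noise is added
    (formant filtering attenuates the open vowels heavily, which would
    waste 16-bit headroom); perturbation features are scale-invariant so
    this does not touch the ground truth.
    """
    wave, pulses = synthesize_pulse_train(params)
    wave = apply_vocal_tract(wave, PHONEME_PROFILES[params.phoneme])
    peak = float(np.max(np.abs(wave.samples)))
    if peak > 0:
        wave = Waveform(wave.samples * (0.5 / peak), wave.sample_rate)
    wave = add_aspiration_noise(wave, params.noise_snr_db, seed=params.seed + 1)
    return wave, pulses


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDistribution:
    """Per-group parameter distributions (mean, spread) for subject draws."""

    f0_mean: float = 140.0
    f0_sd: float = 25.0
    jitter_mean: float = 0.005
    jitter_sd: float = 0.003
    shimmer_mean: float = 0.03
    shimmer_sd: float = 0.015
    snr_mean_db: float = 22.0
    snr_sd_db: float = 4.0


#: Default study conditions.  Controls sit at healthy-voice perturbation
#: levels; the unmedicated PD group has elevated jitter/shimmer and more
#: aspiration noise; the medicated state is interpolated per subject
#: (partial normalization under levodopa).
DEFAULT_GROUPS: dict[str, GroupDistribution] = {
    "CO": GroupDistribution(
        jitter_mean=0.005,
        jitter_sd=0.003,
        shimmer_mean=0.03,
        shimmer_sd=0.015,
        snr_mean_db=22.0,
        snr_sd_db=4.0,
    ),
    "PD-off": GroupDistribution(
        jitter_mean=0.012,
        jitter_sd=0.006,
        shimmer_mean=0.06,
        shimmer_sd=0.03,
        snr_mean_db=15.0,
        snr_sd_db=4.0,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic three-group cohort (CO / PD-off / PD-on)."""

    n_controls: int = 22
    n_patients: int = 24
    phonemes: tuple[str, ...] = ("a", "o", "m")
    duration: float = 5.5
    sample_rate: float = 48000.0
    paired: bool = True
    #: Mean position of PD-on between PD-off (0) and the control mean (1).
    #: Default 0.35: medication recovers only part of the distance to
    #: healthy voice, keeping the on-state closer to off than to control.
    pd_on_fraction: float = 0.35
    #: Between-subject spread of the medication response (drawn per
    #: subject, truncated to [-0.25, 1]); levodopa responses on voice are
    #: notoriously heterogeneous — some patients barely respond or even
    #: worsen — which is what makes the on-vs-off contrast the hardest.
    pd_on_fraction_sd: float = 0.3
    groups: dict[str, GroupDistribution] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be non-negative")
        if not 0.0 <= self.pd_on_fraction <= 1.0:
            raise ValueError("pd_on_fraction must lie in [0, 1]")
        for ph in self.phonemes:
            if ph not in PHONEME_PROFILES:
                raise ValueError(f"unknown phoneme {ph!r}")


@dataclass(frozen=True)
class CohortRecording:
    subject_id: str
    group: str
    phoneme: str
    waveform: Waveform
    params: SynthesisParams


def _truncated_normal(rng, mean, sd, lo, hi):
    """Draw one value, resampling into [lo, hi]."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def synthesize_cohort(config: CohortConfig) -> list[CohortRecording]:
    """Generate one recording per subject x phoneme (PD subjects twice:
    off- and on-medication), with exact ground-truth parameters.

    PD-on parameters are the same subject's PD-off draw pulled toward the
    control-group mean by ``pd_on_fraction`` (f0 is a subject trait and is
    shared between medication states).
    """
    rng = np.random.default_rng(config.master_seed)
    co = config.groups["CO"]
    pd = config.groups["PD-off"]
    recordings: list[CohortRecording] = []

    def draw_subject(dist: GroupDistribution) -> dict[str, float]:
        return {
            "f0": _truncated_normal(rng, dist.f0_mean, dist.f0_sd, 80.0, 260.0),
            "jitter_sigma": _truncated_normal(
                rng, dist.jitter_mean, dist.jitter_sd, 1e-4, 0.15
            ),
            "shimmer_sigma": _truncated_normal(
                rng, dist.shimmer_mean, dist.shimmer_sd, 1e-4, 0.15
            ),
            "noise_snr_db": rng.normal(dist.snr_mean_db, dist.snr_sd_db),
        }

    def emit(subject_id: str, group: str, sub: dict[str, float]) -> None:
        for phoneme in config.phonemes:
            seed = int(rng.integers(0, 2**31 - 1))
            params = SynthesisParams(
                f0=sub["f0"],
                duration=config.duration,
                sample_rate=config.sample_rate,
                jitter_sigma=sub["jitter_sigma"],
                shimmer_sigma=sub["shimmer_sigma"],
                noise_snr_db=sub["noise_snr_db"],
                phoneme=phoneme,
                seed=seed,
            )
            wave, _ = synthesize_phoneme(params)
            recordings.append(CohortRecording(subject_id, group, phoneme, wave, params))

    for i in range(config.n_controls):
        emit(f"co{i:02d}", "CO", draw_subject(co))

    for i in range(config.n_patients):
        off = draw_subject(pd)
        if config.pd_on_fraction_sd > 0:
            frac = _truncated_normal(
                rng, config.pd_on_fraction, config.pd_on_fraction_sd, -0.25, 1.0
            )
        else:
            frac = config.pd_on_fraction
        on = {
            "f0": off["f0"],
            "jitter_sigma": off["jitter_sigma"]
            + frac * (co.jitter_mean - off["jitter_sigma"]),
            "shimmer_sigma": off["shimmer_sigma"]
            + frac * (co.shimmer_mean - off["shimmer_sigma"]),
            "noise_snr_db": off["noise_snr_db"]
            + frac * (co.snr_mean_db - off["noise_snr_db"]),
        }
        sid = f"pd{i:02d}"
        emit(sid, "PD-off", off)
        if config.paired:
            emit(sid, "PD-on", on)

    return recordings


def cohort_manifest(recordings: Iterable[CohortRecording], wav_paths=None):
    """Ground-truth manifest as a DataFrame (all parameters are synthetic
    inventions, labelled as such in the ``provenance`` column)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(recordings):
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "phoneme": rec.phoneme,
                "f0": rec.params.f0,
                "jitter_sigma": rec.params.jitter_sigma,
                "shimmer_sigma": rec.params.shimmer_sigma,
                "noise_snr_db": rec.params.noise_snr_db,
                "seed": rec.params.seed,
                "wav_path": "" if wav_paths is None else wav_paths[i],
                "provenance": "synthetic",
            }
        )
    return pd.DataFrame(rows)


def synthesize_null_features(
    n_co: int,
    n_pd: int,
    n_segments: int = 10,
    phonemes: Sequence[str] = ("a", "o", "m"),
    n_features: int = 16,
    seed: int = 0,
):
    """Feature-level null cohort: every group's rows are i.i.d. draws from
    the same standard normal, so any detected group difference is a false
    positive.  Used for type-I calibration of the significance table and
    for permutation-style classifier nulls.

    Returns (features DataFrame indexed by (subject, group, segment),
    labels Series).
    """
    import pandas as pd

    from .features import CLASSIFIER_FEATURES, EXCLUDED_PITCH_FEATURES

    names = (CLASSIFIER_FEATURES + EXCLUDED_PITCH_FEATURES)[:n_features]
    columns = [f"{ph}_{name}" for ph in phonemes for name in names]
    rng = np.random.default_rng(seed)
    index = []
    for i in range(n_co):
        for s in range(n_segments):
            index.append((f"co{i:02d}", "CO", s))
    for group in ("PD-off", "PD-on"):
        for i in range(n_pd):
            for s in range(n_segments):
                index.append((f"pd{i:02d}", group, s))
    idx = pd.MultiIndex.from_tuples(index, names=["subject", "group", "segment"])
    data = rng.standard_normal((len(idx), len(columns)))
    features = pd.DataFrame(data, index=idx, columns=columns)
    labels = pd.Series([g for _, g, _ in index], index=idx, name="group")
    return features, labels
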