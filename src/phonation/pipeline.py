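"""Recording-to-feature-matrix pipeline.

Protocol: read the WAV, trim to the longest voiced region by short-time
energy, cut ten contiguous 0.5 s segments from the trimmed start (an
evenly-spread alternative is available), extract the per-segment feature
vector, and assemble a subjects x (phoneme x 12 features) matrix with
group labels.  A complete cohort of 22 controls and 24 patients yields a
220 x 36 control block and 240 x 36 blocks for each medication state.

Subjects missing a phoneme, or with any unvoiced/failed segment, are
dropped from the classifier matrix (and counted in the QC report) so the
N_subjects x 10 row structure stays exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import (
    NoVoicedRegionError,
    PhonationError,
    RecordingTooShortError,
    Waveform,
)
from .features import CLASSIFIER_FEATURES, EXCLUDED_PITCH_FEATURES, segment_features
from .pulses import (
    DEFAULT_PITCH_CEILING,
    DEFAULT_PITCH_FLOOR,
    DEFAULT_VOICING_THRESHOLD,
    detect_pulses,
    normalized_autocorrelation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "RecordingMeta",
    "CohortDataset",
    "read_wav",
    "write_wav",
    "trim_recording",
    "segment_recording",
    "extract_segment",
    "build_feature_matrix",
    "build_from_manifest",
    "save_cohort",
]

GROUPS = ("CO", "PD-off", "PD-on")
_PCM_SCALE = 32767.0


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunables of the extraction pipeline."""

    pitch_floor: float = DEFAULT_PITCH_FLOOR
    pitch_ceiling: float = DEFAULT_PITCH_CEILING
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD
    segment_duration: float = 0.5
    n_segments: int = 10
    segment_mode: str = "first"  # or "spread"
    trim_threshold: float = 0.1
    trim_frame: float = 0.025
    phonemes: tuple[str, ...] = ("a", "o", "m")
    #: unbiased autocorrelation for harmonicity (removes the 1-k/L taper
    #: that would otherwise floor NHR at T0/L on short segments)
    unbiased_autocorr: bool = True


@dataclass(frozen=True)
class RecordingMeta:
    subject_id: str
    group: str
    phoneme: str
    path: str = ""


@dataclass(frozen=True)
class CohortDataset:
    """Labeled feature matrix with (subject, group, segment) rows.

    ``features`` holds only the 36 classifier columns (phoneme-major);
    the excluded pitch statistics live in ``pitch_extras`` with the same
    index; ``labels`` maps each row to its group.
    """

    features: pd.DataFrame
    labels: pd.Series
    pitch_extras: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def block(self, group: str) -> pd.DataFrame:
        """The feature sub-matrix of one group (e.g. 220 x 36 for CO)."""
        return self.features.loc[self.labels == group]

    def to_csv(self, path) -> None:
        # group membership travels in the (subject, group, segment) index
        pd.concat([self.features, self.pitch_extras], axis=1).to_csv(
            path, float_format="%.12g"
        )

    @classmethod
    def from_csv(cls, path) -> "CohortDataset":
        df = pd.read_csv(path, index_col=[0, 1, 2])
        labels = pd.Series(
            df.index.get_level_values("group"), index=df.index, name="group"
        )
        extras_cols = [
            c for c in df.columns if c.split("_", 1)[-1] in EXCLUDED_PITCH_FEATURES
        ]
        extras = df[extras_cols]
        return cls(features=df.drop(columns=extras_cols), labels=labels,
                   pitch_extras=extras)


def read_wav(path) -> Waveform:
    """Read a PCM WAV file as a mono float waveform in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise PhonationError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        raise PhonationError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples, float(sr))


def write_wav(path, wave: Waveform) -> None:
    """Write 16-bit PCM mono WAV; samples are clipped to [-1, 1]."""
    clipped = np.clip(wave.samples, -1.0, 1.0)
    wavfile.write(path, int(round(wave.sample_rate)), (clipped * _PCM_SCALE).astype(np.int16))


def trim_recording(
    wave: Waveform, energy_threshold: float = 0.1, frame_duration: float = 0.025
) -> Waveform:
    """Longest contiguous run of frames above threshold x median energy."""
    frame = max(int(round(frame_duration * wave.sample_rate)), 1)
    n_frames = len(wave) // frame
    if n_frames == 0:
        raise NoVoicedRegionError("recording shorter than one analysis frame")
    x = wave.samples[: n_frames * frame].reshape(n_frames, frame)
    energy = np.mean(x**2, axis=1)
    ref = float(np.median(energy))
    active = energy > energy_threshold * ref
    if ref == 0.0 or not np.any(active):
        raise NoVoicedRegionError("no frame exceeds the energy threshold")
    # longest run of True
    best_len, best_start = 0, 0
    run_start = None
    for i, a in enumerate(np.append(active, False)):
        if a and run_start is None:
            run_start = i
        elif not a and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    lo = best_start * frame
    hi = (best_start + best_len) * frame
    if best_start + best_len == n_frames:  # include the ragged tail
        hi = len(wave)
    return Waveform(wave.samples[lo:hi], wave.sample_rate)


def segment_recording(
    wave: Waveform,
    n_segments: int = 10,
    segment_duration: float = 0.5,
    mode: str = "first",
) -> list[Waveform]:
    """Cut ``n_segments`` non-overlapping windows of ``segment_duration``.

    ``mode='first'`` takes contiguous windows [k*d, (k+1)*d) from the
    start; ``mode='spread'`` spaces the window starts evenly over the
    recording.  Raises :class:`RecordingTooShortError` below
    ``n_segments * segment_duration`` seconds.
    """
    needed = n_segments * segment_duration
    if wave.duration < needed - 0.5 / wave.sample_rate:
        raise RecordingTooShortError(
            f"recording of {wave.duration:.2f}s is shorter than {needed:.1f}s"
        )
    seg_len = int(round(segment_duration * wave.sample_rate))
    if mode == "first":
        starts = [k * seg_len for k in range(n_segments)]
    elif mode == "spread":
        last = len(wave) - seg_len
        starts = [int(round(k * last / (n_segments - 1))) for k in range(n_segments)]
    else:
        raise ValueError(f"unknown segment mode {mode!r}")
    return [
        Waveform(wave.samples[s : s + seg_len], wave.sample_rate) for s in starts
    ]


def extract_segment(wave: Waveform, config: ExtractionConfig) -> dict[str, float]:
    """Feature vector of one voiced 0.5 s segment."""
    pulses = detect_pulses(
        wave,
        pitch_floor=config.pitch_floor,
        pitch_ceiling=config.pitch_ceiling,
        voicing_threshold=config.voicing_threshold,
    )
    prof = normalized_autocorrelation(
        wave,
        pitch_floor=config.pitch_floor,
        pitch_ceiling=config.pitch_ceiling,
        unbiased=config.unbiased_autocorr,
    )
    return segment_features(pulses, prof.r_t0)


def _extract_recording(wave: Waveform, config: ExtractionConfig) -> list[dict[str, float]]:
    trimmed = trim_recording(wave, config.trim_threshold, config.trim_frame)
    segments = segment_recording(
        trimmed, config.n_segments, config.segment_duration, config.segment_mode
    )
    return [extract_segment(seg, config) for seg in segments]


def build_feature_matrix(
    records: Iterable[tuple[RecordingMeta, Waveform]],
    config: ExtractionConfig | None = None,
) -> CohortDataset:
    """Assemble the labeled cohort matrix from (meta, waveform) pairs.

    One row per (subject, group, segment); classifier columns are
    phoneme-major in the fixed feature order.  Subjects with a missing
    phoneme or any failed segment are dropped (recorded in ``qc``).
    """
    config = config or ExtractionConfig()
    phonemes = config.phonemes
    per_subject: dict[tuple[str, str], dict[str, list[dict]]] = {}
    failures: dict[tuple[str, str], str] = {}

    for meta, wave in records:
        key = (meta.subject_id, meta.group)
        if key in failures:
            continue
        try:
            rows = _extract_recording(wave, config)
        except PhonationError as exc:
            failures[key] = f"{meta.phoneme}: {exc}"
            per_subject.pop(key, None)
            logger.warning("dropping subject %s (%s): %s", meta.subject_id, meta.group, exc)
            continue
        per_subject.setdefault(key, {})[meta.phoneme] = rows

    incomplete = {
        key: f"missing phoneme(s): {sorted(set(phonemes) - set(v))}"
        for key, v in per_subject.items()
        if set(phonemes) - set(v)
    }
    for key, reason in incomplete.items():
        per_subject.pop(key)
        logger.warning("dropping subject %s (%s): %s", key[0], key[1], reason)
    failures.update(incomplete)

    classifier_cols = [f"{ph}_{f}" for ph in phonemes for f in CLASSIFIER_FEATURES]
    extra_cols = [f"{ph}_{f}" for ph in phonemes for f in EXCLUDED_PITCH_FEATURES]
    index, feat_rows, extra_rows = [], [], []
    for (subject, group) in sorted(per_subject):
        by_phoneme = per_subject[(subject, group)]
        for seg in range(config.n_segments):
            row = {}
            for ph in phonemes:
                for name, value in by_phoneme[ph][seg].items():
                    row[f"{ph}_{name}"] = value
            index.append((subject, group, seg))
            feat_rows.append([row[c] for c in classifier_cols])
            extra_rows.append([row[c] for c in extra_cols])

    idx = pd.MultiIndex.from_tuples(index, names=["subject", "group", "segment"])
    features = pd.DataFrame(feat_rows, index=idx, columns=classifier_cols)
    extras = pd.DataFrame(extra_rows, index=idx, columns=extra_cols)
    if features.isna().any().any():
        bad = features.isna().any(axis=1)
        dropped_subjects = sorted({(s, g) for s, g, _ in features.index[bad]})
        for s, g in dropped_subjects:
            failures[(s, g)] = "missing feature value"
            keep = ~((features.index.get_level_values(0) == s)
                     & (features.index.get_level_values(1) == g))
            features, extras = features[keep], extras[keep]
    labels = pd.Series(features.index.get_level_values("group"), index=features.index,
                       name="group")
    qc = {
        "n_rows": int(len(features)),
        "dropped_subjects": {f"{s}/{g}": reason for (s, g), reason in sorted(failures.items())},
    }
    return CohortDataset(features=features, labels=labels, pitch_extras=extras, qc=qc)


def build_from_manifest(manifest_csv, config: ExtractionConfig | None = None) -> CohortDataset:
    """Build the cohort matrix from a manifest CSV referencing WAV files.

    Required columns: subject_id, group, phoneme, wav_path (relative
    paths resolve against the manifest's directory).
    """
    manifest = pd.read_csv(manifest_csv)
    base = Path(manifest_csv).parent

    def records():
        for rec in manifest.itertuples(index=False):
            path = Path(rec.wav_path)
            if not path.is_absolute():
                path = base / path
            meta = RecordingMeta(str(rec.subject_id), rec.group, rec.phoneme, str(path))
            yield meta, read_wav(path)

    return build_feature_matrix(records(), config)


def save_cohort(recordings, outdir) -> Path:
    """Write cohort WAVs plus the ground-truth manifest; returns the
    manifest path."""
    from .synth import cohort_manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        name = f"{rec.subject_id}_{rec.group.replace('-', '')}_{rec.phoneme}.wav"
        write_wav(outdir / name, rec.waveform)
        paths.append(name)
    manifest = cohort_manifest(recordings, wav_paths=paths)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.12g")
    return manifest_path
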