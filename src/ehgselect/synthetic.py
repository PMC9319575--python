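"""Synthetic EHG cohorts and controllable feature tables.

Real term/preterm EHG datasets are public but large and cannot be bundled;
this module generates cohorts with the same statistical skeleton so every
downstream stage (filtering, feature extraction, resampling, GA selection,
evaluation) is testable offline:

* 3 bipolar channels sampled at 20 Hz, pink-noise baseline band-limited to
  0.1-4 Hz with Poisson-placed contraction-like bursts (Gaussian-windowed
  oscillations, carrier 0.2-0.8 Hz) shared across channels;
* class effects as multiplicative shifts of overall amplitude, burst
  carrier frequency and burst regularity for preterm records;
* annotated high-amplitude artifact segments covering a controllable
  fraction of the record;
* obstetric covariates from plausible ranges with no class effect, so any
  discriminative signal in tests comes from the waveforms;
* a 51 preterm : 275 term default composition (16 % minority).

For tests that exercise the classifier stack directly, ``generate_feature_
table`` builds Gaussian tables with a known Mahalanobis separation between
classes and labelled informative/noise columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureTable
from .preprocessing import WINDOW_LENGTH_S, bandpass

logger = logging.getLogger("ehgselect")

#: baseline (non-burst) signal scale, microvolt
BASELINE_STD_UV = 10.0
#: burst oscillation amplitude scale, microvolt
BURST_AMP_UV = 40.0
#: artifact transient amplitude, microvolt
ARTIFACT_AMP_UV = 300.0


@dataclass
class ClassEffect:
    """Multiplicative preterm-vs-term shifts (1.0 = no effect)."""

    amplitude_shift: float = 1.3
    frequency_shift: float = 1.15
    regularity_shift: float = 1.3

    def __post_init__(self):
        if min(self.amplitude_shift, self.frequency_shift, self.regularity_shift) <= 0:
            raise ValueError("class-effect shifts must be > 0")


@dataclass
class EHGRecord:
    """One multichannel EHG recording with annotations and covariates."""

    record_id: str
    signals: np.ndarray  # (3, n) microvolt
    fs: float
    artifact_intervals: list[tuple[float, float]]
    obstetrics: dict[str, float]
    label: str  # "preterm" | "term"

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signals.ndim != 2 or self.signals.shape[0] != 3:
            raise ValueError("signals must have exactly 3 channels of equal length")
        dur = self.duration_s
        for a, b in self.artifact_intervals:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"artifact interval [{a}, {b}) outside [0, {dur}]")
        wog = self.obstetrics.get("weeks_of_gestation")
        if wog is not None and not (22 <= wog <= 37):
            raise ValueError("weeks_of_gestation must lie in [22, 37]")
        if self.label not in ("preterm", "term"):
            raise ValueError("label must be 'preterm' or 'term'")

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.fs


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the real ensemble database composition (51 preterm vs
    275 term) with 30-minute records; class effects are moderate so the
    classes overlap, as they do in recordings taken far from delivery.
    """

    n_preterm: int = 51
    n_term: int = 275
    duration_s: float = 1800.0
    fs: float = 20.0
    burst_rate: float = 0.5  # bursts per minute
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    artifact_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_preterm < 1 or self.n_term < 1:
            raise ValueError("cohort needs at least one record per class")
        if not (0 <= self.artifact_fraction < 1):
            raise ValueError("artifact_fraction must lie in [0, 1)")


@dataclass
class TableSpec:
    """Gaussian feature-table parameters (classifier-stack plumbing)."""

    n_minority: int = 51
    n_majority: int = 275
    n_informative: int = 5
    n_noise: int = 45
    separation: float = 2.0  # Mahalanobis distance between class means
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValueError("counts must be >= 1")


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude noise band-limited to 0.1-4 Hz, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * scale, n=n)
    x = bandpass(x, fs, 0.1, 4.0)
    sd = x.std()
    return x / sd if sd > 0 else x


def _place_artifacts(
    rng: np.random.Generator, duration: float, fraction: float
) -> list[tuple[float, float]]:
    """Non-overlapping dirty intervals covering ~= fraction of the record."""
    target = fraction * duration
    intervals: list[tuple[float, float]] = []
    covered = 0.0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        length = min(rng.uniform(10.0, 60.0), target - covered + 10.0)
        start = rng.uniform(0.0, duration - length)
        if any(start < b and start + length > a for a, b in intervals):
            continue
        intervals.append((start, start + length))
        covered += length
    return sorted(intervals)


def generate_record(class_label: str, spec: CohortSpec, seed: int,
                    record_id: str | None = None) -> EHGRecord:
    """One synthetic EHG record, fully determined by ``seed``.

    Baseline pink noise plus burst events shared across the 3 channels;
    preterm records get the whole signal scaled by ``amplitude_shift``,
    burst carriers scaled by ``frequency_shift`` and burst phase jitter
    divided by ``regularity_shift``. Artifact transients are added on top
    and recorded in ``artifact_intervals``.
    """
    if class_label not in ("preterm", "term"):
        raise ValueError("class_label must be 'preterm' or 'term'")
    if spec.duration_s < WINDOW_LENGTH_S:
        raise ValueError(
            f"duration {spec.duration_s} s shorter than one "
            f"{WINDOW_LENGTH_S:.0f} s analysis window")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    preterm = class_label == "preterm"
    eff = spec.class_effect

    signals = np.stack([BASELINE_STD_UV * _pink_noise(rng, n, fs) for _ in range(3)])

    # shared burst times; per-channel amplitude variation
    n_bursts = rng.poisson(spec.burst_rate * spec.duration_s / 60.0)
    freq_shift = eff.frequency_shift if preterm else 1.0
    jitter_scale = (1.0 / eff.regularity_shift) if preterm else 1.0
    for _ in range(n_bursts):
        center = rng.uniform(0.0, spec.duration_s)
        width = rng.uniform(20.0, 45.0)  # Gaussian envelope SD/2 heuristic
        f0 = rng.uniform(0.2, 0.8) * freq_shift
        envelope = np.exp(-0.5 * ((t - center) / (width / 2.0)) ** 2)
        # carrier with integrated phase noise (lower regularity = more jitter)
        dphi = 2 * np.pi * f0 / fs + jitter_scale * 0.15 * rng.standard_normal(n)
        phase = np.cumsum(dphi)
        carrier = np.sin(phase + rng.uniform(0, 2 * np.pi))
        for ch in range(3):
            amp = BURST_AMP_UV * rng.uniform(0.7, 1.3)
            signals[ch] += amp * envelope * carrier

    if preterm:
        signals *= eff.amplitude_shift

    intervals = _place_artifacts(rng, spec.duration_s, spec.artifact_fraction)
    for a, b in intervals:
        i0, i1 = int(a * fs), int(b * fs)
        seg_t = t[i0:i1] - a
        # low-frequency motion transient plus spiky noise
        transient = ARTIFACT_AMP_UV * np.sin(2 * np.pi * 0.05 * seg_t + rng.uniform(0, 2 * np.pi))
        for ch in range(3):
            spikes = ARTIFACT_AMP_UV * 0.5 * rng.standard_normal(i1 - i0)
            signals[ch, i0:i1] += transient + spikes

    obstetrics = {
        "maternal_age": float(np.clip(rng.normal(30.0, 4.0), 18.0, 45.0)),
        "parity": float(rng.poisson(1.0)),
        "abortions": float(rng.poisson(0.3)),
        "weight": float(np.clip(rng.normal(70.0, 12.0), 45.0, 120.0)),
        "weeks_of_gestation": float(rng.uniform(22.5, 36.5)),
    }
    return EHGRecord(
        record_id=record_id or f"{class_label[0].upper()}{seed:08d}",
        signals=signals, fs=fs, artifact_intervals=intervals,
        obstetrics=obstetrics, label=class_label,
    )


def record_seed(master_seed: int, index: int) -> int:
    """Deterministic per-record seed, stable under cohort extension."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))


def generate_cohort(spec: CohortSpec) -> list[EHGRecord]:
    """Exactly n_preterm + n_term records with seeds derived from spec.seed."""
    records = []
    for i in range(spec.n_preterm):
        records.append(generate_record(
            "preterm", spec, record_seed(spec.seed, i), record_id=f"P{i + 1:03d}"))
    for i in range(spec.n_term):
        records.append(generate_record(
            "term", spec, record_seed(spec.seed, spec.n_preterm + i),
            record_id=f"T{i + 1:03d}"))
    return records


def generate_feature_table(spec: TableSpec) -> FeatureTable:
    """Two-class Gaussian table with known informative columns.

    Informative features are unit-variance Gaussians whose class means
    differ by ``separation`` in Mahalanobis distance (the shift is spread
    evenly, separation/sqrt(n_informative) per column); noise features are
    identically distributed in both classes. Column names flag ground
    truth: ``inf_*`` vs ``noise_*``; label 1 = minority (preterm).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    p = spec.n_informative + spec.n_noise
    n = spec.n_minority + spec.n_majority
    X = rng.standard_normal((n, p))
    if spec.n_informative > 0:
        shift = spec.separation / np.sqrt(spec.n_informative)
        X[:spec.n_minority, :spec.n_informative] += shift
    labels = np.concatenate([
        np.ones(spec.n_minority, dtype=int), np.zeros(spec.n_majority, dtype=int)])
    names = [f"inf_{i:02d}" for i in range(spec.n_informative)] + \
            [f"noise_{i:02d}" for i in range(spec.n_noise)]
    return FeatureTable(X, names, labels)


def informative_indices(table: FeatureTable) -> np.ndarray:
    """Ground-truth informative column indices of a generated table."""
    return np.array([i for i, n in enumerate(table.feature_names)
                     if n.startswith("inf_")])


# ---------------------------------------------------------------------------
# on-disk layout: one numeric file per channel + JSON sidecar + manifest
# ---------------------------------------------------------------------------

def write_record(record: EHGRecord, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch in range(3):
        np.savetxt(directory / f"{record.record_id}_ch{ch + 1}.txt",
                   record.signals[ch], fmt="%.6f")
    header = {
        "record_id": record.record_id,
        "fs": record.fs,
        "n_samples": int(record.signals.shape[1]),
        "artifact_intervals": [[a, b] for a, b in record.artifact_intervals],
        "obstetrics": record.obstetrics,
        "label": record.label,
    }
    (directory / f"{record.record_id}.json").write_text(json.dumps(header, indent=1))


def read_record(directory, record_id: str) -> EHGRecord:
    directory = Path(directory)
    header = json.loads((directory / f"{record_id}.json").read_text())
    signals = np.stack([
        np.loadtxt(directory / f"{record_id}_ch{ch + 1}.txt") for ch in range(3)])
    return EHGRecord(
        record_id=header["record_id"], signals=signals, fs=header["fs"],
        artifact_intervals=[tuple(iv) for iv in header["artifact_intervals"]],
        obstetrics=header["obstetrics"], label=header["label"],
    )


def write_cohort(records: list[EHGRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["record_id,label,duration_s,n_artifact_intervals"]
    for rec in records:
        write_record(rec, directory)
        lines.append(f"{rec.record_id},{rec.label},{rec.duration_s:.1f},"
                     f"{len(rec.artifact_intervals)}")
    (directory / "manifest.csv").write_text("\n".join(lines) + "\n")
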