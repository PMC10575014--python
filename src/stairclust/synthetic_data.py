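"""Synthetic fixtures: cluster-geometry embeddings and gait recordings.

Two families of generators make every pipeline stage testable without the
deposited recordings:

* :func:`gen_embedding` draws 2-D point clouds directly, with the cluster
  geometry the stair-identification hypotheses describe — one dominant
  walking cluster (90–99% of points), one stair cluster that is the most
  distant and most compact, and optional extraneous walking clusters
  closer in and more diffuse.
* :func:`gen_recording` synthesizes tri-axial thigh acceleration as a
  harmonic series per activity bout (fundamental at the activity's
  cadence plus two harmonics plus Gaussian noise).  Stair bouts use a
  markedly lower cadence than ground walking, reflecting the slower,
  more deliberate gait stairs require; uphill/downhill cadences sit within
  a small offset of flat walking.

Gait is modeled as harmonics + noise rather than a biomechanical
simulation: the pipeline only consumes windowed time/frequency statistics,
and the harmonic model drives all of them.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from stairclust.embedding import Embedding
from stairclust.ingest import LabelTrack, Recording

# ---------------------------------------------------------------------------
# 2-D embedding geometry


@dataclass
class EmbeddingSpec:
    """Geometry of a synthetic 2-D embedding.

    The invariants mirror the stair hypotheses: the walking cluster holds
    90–99% of the points; the stair cluster is tighter than the walking
    cluster and farther from it than any extraneous cluster.
    """

    n_total: int = 1000
    stair_fraction: float = 0.05
    walk_center: tuple[float, float] = (0.0, 0.0)
    stair_center: tuple[float, float] = (30.0, 0.0)
    walk_spread: float = 5.0
    stair_spread: float = 1.5
    extraneous: list[tuple[tuple[float, float], float, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not (0.01 <= self.stair_fraction <= 0.10):
            raise ValueError("stair_fraction must be in [0.01, 0.10]")
        if self.stair_spread >= self.walk_spread:
            raise ValueError("stair cluster must be more compact than the walking cluster")
        wc = np.asarray(self.walk_center)
        stair_d = np.linalg.norm(np.asarray(self.stair_center) - wc)
        for center, spread, size in self.extraneous:
            if np.linalg.norm(np.asarray(center) - wc) >= stair_d:
                raise ValueError(
                    "extraneous clusters must be closer to the walking cluster than stairs"
                )
            if size < 1 or spread <= 0:
                raise ValueError("extraneous sizes/spreads must be positive")
        n_extr = sum(size for _, _, size in self.extraneous)
        n_stair = round(self.n_total * self.stair_fraction)
        if n_stair + n_extr >= self.n_total:
            raise ValueError("stair + extraneous points exceed n_total")


def gen_embedding(spec: EmbeddingSpec) -> tuple[Embedding, list[str]]:
    """Draw one isotropic Gaussian blob per cluster; reproducible under seed.

    Returns the embedding and per-point true identities: ``walk``,
    ``stair`` or ``extraneous_<i>``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_stair = round(spec.n_total * spec.stair_fraction)
    n_extr = sum(size for _, _, size in spec.extraneous)
    n_walk = spec.n_total - n_stair - n_extr
    pts = [rng.normal(spec.walk_center, spec.walk_spread, size=(n_walk, 2))]
    labels = ["walk"] * n_walk
    pts.append(rng.normal(spec.stair_center, spec.stair_spread, size=(n_stair, 2)))
    labels += ["stair"] * n_stair
    for i, (center, spread, size) in enumerate(spec.extraneous, start=1):
        pts.append(rng.normal(center, spread, size=(size, 2)))
        labels += [f"extraneous_{i}"] * size
    Y = np.vstack(pts)
    emb = Embedding(
        Y=Y,
        seed=spec.seed,
        params={"generator": "synthetic-gaussian-geometry"},
        labels=["upstairs" if l == "stair" else "flat" for l in labels],
        subject_id="synthetic",
    )
    return emb, labels


# ---------------------------------------------------------------------------
# harmonic gait recordings


@dataclass
class GaitParams:
    """Harmonic gait model for one activity.

    ``cadence`` is the fundamental frequency of thigh acceleration in Hz
    (≈ stride rate); ``amplitude`` the fundamental's peak value in g.
    ``harmonics`` are relative amplitudes of the 2nd and 3rd harmonics and
    ``axis_mix`` scales the waveform per axis (thigh placement makes the
    longitudinal axis dominate).
    """

    cadence: float
    amplitude: float
    harmonics: tuple[float, float] = (0.4, 0.15)
    axis_mix: tuple[float, float, float] = (1.0, 0.6, 0.35)
    noise_sd: float = 0.08
    cadence_drift: float = 0.04  # relative s.d. of slow within-bout cadence drift
    amplitude_drift: float = 0.08


#: per-activity defaults: ground walking near 1.8 Hz with small hill
#: offsets, stairs at roughly half the cadence with larger thigh excursion
DEFAULT_GAIT: dict[str, GaitParams] = {
    "flat": GaitParams(cadence=1.80, amplitude=0.35, cadence_drift=0.08, amplitude_drift=0.15),
    "uphill": GaitParams(cadence=1.74, amplitude=0.38, cadence_drift=0.08, amplitude_drift=0.15),
    "downhill": GaitParams(cadence=1.86, amplitude=0.33, cadence_drift=0.08, amplitude_drift=0.15),
    "upstairs": GaitParams(cadence=0.95, amplitude=0.55, harmonics=(0.5, 0.2), cadence_drift=0.05),
    "downstairs": GaitParams(cadence=1.05, amplitude=0.5, harmonics=(0.5, 0.2), cadence_drift=0.05),
}

GRAVITY_OFFSET = (0.95, 0.2, 0.1)  # quasi-static g projection per axis


@dataclass
class SignalSpec:
    """Bout schedule plus per-activity gait parameters for one subject."""

    schedule: list[tuple[str, float]] = field(default_factory=list)  # (activity, seconds)
    gait: dict[str, GaitParams] = field(default_factory=lambda: dict(DEFAULT_GAIT))
    sampling_rate: float = 20.0
    subject_id: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must be non-empty")
        for act, dur in self.schedule:
            if act not in self.gait:
                raise ValueError(f"no gait parameters for activity {act!r}")
            if dur <= 0:
                raise ValueError("bout durations must be positive")
        ground = [self.gait[a].cadence for a in ("flat", "uphill", "downhill") if a in self.gait]
        stairs = [self.gait[a].cadence for a in ("upstairs", "downstairs") if a in self.gait]
        if ground and stairs and min(ground) <= max(stairs):
            raise ValueError("stair cadence must be below ground-walking cadence")


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, tau_s: float = 5.0) -> np.ndarray:
    """Unit-variance slowly varying noise (moving-average smoothed white noise)."""
    width = max(1, int(round(tau_s * fs)))
    w = rng.normal(size=n + width)
    kernel = np.ones(width) / width
    sm = np.convolve(w, kernel, mode="valid")[:n]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def gen_recording(spec: SignalSpec) -> tuple[Recording, LabelTrack]:
    """Synthesize a labelled tri-axial recording from a bout schedule.

    Each bout is a fundamental sinusoid at the activity's cadence plus two
    harmonics plus white noise per axis, offset by a static gravity
    projection (removed downstream by the band-pass filter).  The axis
    phase relationships are drawn once per subject so the waveform shape —
    and hence the axis-correlation features — is stable across bouts of
    the same activity, as it is for a real wearer; cadence and amplitude
    drift slowly within bouts to emulate natural gait variability.  Label
    intervals match the schedule exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    # subject-level waveform identity: fixed inter-axis and harmonic phases
    axis_phase = rng.uniform(0, 2 * np.pi, size=3)
    harm_phase = rng.uniform(0, 2 * np.pi, size=(3, 2))
    chunks: list[np.ndarray] = []
    intervals: list[tuple[float, float, str]] = []
    t0 = 0.0
    for act, dur in spec.schedule:
        n = int(round(dur * fs))
        gp = spec.gait[act]
        inst_f = gp.cadence * (1.0 + gp.cadence_drift * _smooth_noise(rng, n, fs))
        phase = 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)
        amp = gp.amplitude * (1.0 + gp.amplitude_drift * _smooth_noise(rng, n, fs))
        sig = np.empty((n, 3))
        for ax in range(3):
            base = (
                np.sin(phase + axis_phase[ax])
                + gp.harmonics[0] * np.sin(2 * phase + harm_phase[ax, 0])
                + gp.harmonics[1] * np.sin(3 * phase + harm_phase[ax, 1])
            )
            sig[:, ax] = (
                GRAVITY_OFFSET[ax]
                + amp * gp.axis_mix[ax] * base
                + rng.normal(0, gp.noise_sd, size=n)
            )
        chunks.append(sig)
        intervals.append((t0, t0 + dur, act))
        t0 += dur
    accel = np.vstack(chunks)
    t = np.arange(len(accel)) / fs
    rec = Recording(
        subject_id=spec.subject_id,
        t=t,
        accel=accel,
        sampling_rate=fs,
    )
    return rec, LabelTrack(intervals=intervals)


def default_schedule(
    total_minutes: float = 140.0, stair_fraction: float = 0.05
) -> list[tuple[str, float]]:
    """Free-living-style bout schedule: long ground-walking bouts with
    short interspersed stair bouts.

    Built from repeated 700 s units whose stair share equals
    ``stair_fraction`` exactly (bout arithmetic, no sampling).
    """
    unit = 700.0
    stair_per_unit = unit * stair_fraction
    up = stair_per_unit / 2
    down = stair_per_unit - up
    walk_time = unit - stair_per_unit
    flat = walk_time * 0.5
    uphill = walk_time * 0.25
    downhill = walk_time * 0.25
    n_units = max(1, int(round(total_minutes * 60 / unit)))
    schedule: list[tuple[str, float]] = []
    for _ in range(n_units):
        schedule += [
            ("flat", flat / 2),
            ("uphill", uphill),
            ("upstairs", up),
            ("flat", flat / 2),
            ("downhill", downhill),
            ("downstairs", down),
        ]
    return schedule


def jitter_gait(
    gait: dict[str, GaitParams],
    rng: np.random.Generator,
    cadence_jitter: float = 0.12,
    amplitude_jitter: float = 0.2,
) -> dict[str, GaitParams]:
    """Per-subject idiosyncrasy: shift all cadences together and scale
    amplitudes, preserving the stairs-slower-than-walking ordering."""
    shift = rng.uniform(-cadence_jitter, cadence_jitter)
    scale = 1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter)
    out = {}
    for act, gp in gait.items():
        out[act] = replace(
            gp,
            cadence=gp.cadence + shift,
            amplitude=gp.amplitude * scale,
            noise_sd=gp.noise_sd * (1.0 + rng.uniform(-0.3, 0.3)),
        )
    return out


def gen_cohort(
    n_subjects: int,
    total_minutes: float = 140.0,
    stair_fraction: float = 0.05,
    seed: int = 0,
    cadence_jitter: float = 0.12,
    amplitude_jitter: float = 0.2,
) -> list[tuple[Recording, LabelTrack]]:
    """Generate ``n_subjects`` jittered subjects with the default schedule.

    Inter-subject jitter makes pooled embeddings cluster by subject rather
    than by activity, the reason the pipeline models each subject alone.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        gait = jitter_gait(DEFAULT_GAIT, rng, cadence_jitter, amplitude_jitter)
        spec = SignalSpec(
            schedule=default_schedule(total_minutes, stair_fraction),
            gait=gait,
            subject_id=f"S{i + 1}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(gen_recording(spec))
    return out


def write_fixture_csvs(rec: Recording, track: LabelTrack, rec_path, label_path) -> None:
    """Write a recording + labels in the CSV formats the ingest module reads."""
    import pandas as pd

    pd.DataFrame(
        {"time": rec.t, "x": rec.accel[:, 0], "y": rec.accel[:, 1], "z": rec.accel[:, 2]}
    ).to_csv(rec_path, index=False)
    pd.DataFrame(
        [(s, e, l) for s, e, l in track.intervals], columns=["start", "end", "label"]
    ).to_csv(label_path, index=False)
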