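"""Band-pass filtering, windowing, feature extraction and standardization.

The raw signal is band-pass filtered to 0.4–3 Hz, removing the
gravitational (near-DC) component and high-frequency muscle artifact while
preserving the gait fundamental and its low harmonics.  The filtered
signal is cut into non-overlapping 2 s windows (40 samples at 20 Hz) and a
bank of time- and frequency-domain features is computed per window, then
z-scored per subject.

The feature bank is a named registry evaluated in declared order.  The
default bank covers per-axis time-domain statistics, per-axis spectral
features on the window FFT, pairwise axis correlations, and the same
time-domain statistics on the resultant magnitude.  The exact bank used is
recorded in the :class:`FeatureTable` metadata for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from stairclust.ingest import LabelTrack, Recording, ResolutionLevel, window_labels

AXES = ("x", "y", "z")

#: frequency bands (Hz) for band-power features, matching the filter pass band
DEFAULT_BANDS = ((0.4, 1.0), (1.0, 2.0), (2.0, 3.0))


@dataclass
class WindowSet:
    """Non-overlapping fixed-width windows of filtered acceleration."""

    windows: np.ndarray  # (n, samples_per_window, 3)
    window_starts: np.ndarray  # seconds
    labels: list[str]
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.windows.ndim != 3 or self.windows.shape[2] != 3:
            raise ValueError("windows must be (n, width, 3)")
        if len(self.windows) != len(self.labels):
            raise ValueError("window/label count mismatch")

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class FeatureTable:
    """Per-window feature matrix with ground-truth labels.

    After :func:`standardize`, each non-constant column has zero mean and
    unit sample standard deviation; constant columns are zeroed and listed
    in ``constant_columns``.
    """

    X: np.ndarray  # (n_windows, n_features)
    feature_names: list[str]
    labels: list[str]
    subject_id: str = ""
    standardized: bool = False
    constant_columns: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature name count mismatch")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("label count mismatch")
        if np.isnan(self.X).any():
            raise ValueError("FeatureTable contains NaN")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


class ParameterError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


def bandpass_filter(rec: Recording, low: float = 0.4, high: float = 3.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass of all three axes.

    Forward-backward filtering keeps the output aligned with the ground
    truth intervals (no group delay).  Gains: ~1 in the pass band, ~0 at DC
    and above ``high``.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high):
        raise ParameterError("need 0 < low < high")
    if high >= nyq:
        raise ParameterError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, rec.accel, axis=0)
    return Recording(
        subject_id=rec.subject_id,
        t=rec.t,
        accel=filtered,
        sampling_rate=rec.sampling_rate,
        placement=rec.placement,
        warnings=list(rec.warnings),
    )


def segment_windows(
    rec: Recording,
    track: LabelTrack,
    window_len: float = 2.0,
    level: ResolutionLevel = ResolutionLevel.LEVEL0,
) -> WindowSet:
    """Cut the recording into non-overlapping ``window_len`` s windows.

    The trailing partial window is dropped.  Labels are attached by
    majority duration via :func:`stairclust.ingest.window_labels`.
    """
    width = int(round(window_len * rec.sampling_rate))
    n = len(rec) // width
    if n < 1:
        raise EmptyInputError(
            f"recording of {len(rec)} samples shorter than one {width}-sample window"
        )
    windows = rec.accel[: n * width].reshape(n, width, 3)
    starts = rec.t[0] + np.arange(n) * window_len
    labels = window_labels(track, starts, window_len, level)
    return WindowSet(
        windows=windows,
        window_starts=starts,
        labels=labels,
        sampling_rate=rec.sampling_rate,
        subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# feature bank


def _safe_skew(v: np.ndarray) -> float:
    return 0.0 if np.std(v) < 1e-12 else float(sp_stats.skew(v))


def _safe_kurtosis(v: np.ndarray) -> float:
    return 0.0 if np.std(v) < 1e-12 else float(sp_stats.kurtosis(v))


def _zero_crossings(v: np.ndarray) -> float:
    s = np.sign(v)
    return float(np.sum(np.abs(np.diff(s[s != 0])) > 0)) if np.any(s != 0) else 0.0


def _time_domain(v: np.ndarray, prefix: str) -> dict[str, float]:
    q75, q25 = np.percentile(v, [75, 25])
    return {
        f"{prefix}_mean": float(np.mean(v)),
        f"{prefix}_var": float(np.var(v)),
        f"{prefix}_std": float(np.std(v)),
        f"{prefix}_rms": float(np.sqrt(np.mean(v**2))),
        f"{prefix}_min": float(np.min(v)),
        f"{prefix}_max": float(np.max(v)),
        f"{prefix}_range": float(np.ptp(v)),
        f"{prefix}_iqr": float(q75 - q25),
        f"{prefix}_skew": _safe_skew(v),
        f"{prefix}_kurtosis": _safe_kurtosis(v),
        f"{prefix}_zero_crossings": _zero_crossings(v),
        f"{prefix}_sma": float(np.mean(np.abs(v))),
        f"{prefix}_energy": float(np.sum(v**2)),
    }


def _freq_domain(v: np.ndarray, fs: float, prefix: str) -> dict[str, float]:
    n = len(v)
    spec = np.abs(np.fft.rfft(v)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    pos = spec[1:]  # exclude DC for dominance and entropy
    out: dict[str, float] = {}
    if pos.sum() < 1e-24:
        out[f"{prefix}_dom_freq"] = 0.0
        out[f"{prefix}_dom_power"] = 0.0
        out[f"{prefix}_spec_entropy"] = 0.0
    else:
        k = int(np.argmax(pos)) + 1
        out[f"{prefix}_dom_freq"] = float(freqs[k])
        out[f"{prefix}_dom_power"] = float(spec[k])
        p = pos / pos.sum()
        nz = p[p > 0]
        out[f"{prefix}_spec_entropy"] = float(-np.sum(nz * np.log2(nz)))
    for lo, hi in DEFAULT_BANDS:
        mask = (freqs >= lo) & (freqs < hi) if hi < fs / 2 else (freqs >= lo) & (freqs <= hi)
        out[f"{prefix}_bandpower_{lo:g}_{hi:g}"] = float(spec[mask].sum())
    return out


def _correlations(w: np.ndarray) -> dict[str, float]:
    out = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        a, b = w[:, i], w[:, j]
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            out[f"corr_{AXES[i]}{AXES[j]}"] = 0.0  # convention for constant channels
        else:
            out[f"corr_{AXES[i]}{AXES[j]}"] = float(np.corrcoef(a, b)[0, 1])
    return out


def default_feature_bank() -> list[str]:
    """Ordered names of the extractors in the default bank."""
    return (
        [f"time_{ax}" for ax in AXES]
        + [f"freq_{ax}" for ax in AXES]
        + ["correlations", "time_magnitude"]
    )


def _extract_one(w: np.ndarray, fs: float, extractor: str) -> dict[str, float]:
    if extractor.startswith("time_") and extractor != "time_magnitude":
        ax = extractor.split("_")[1]
        return _time_domain(w[:, AXES.index(ax)], ax)
    if extractor.startswith("freq_"):
        ax = extractor.split("_")[1]
        return _freq_domain(w[:, AXES.index(ax)], fs, ax)
    if extractor == "correlations":
        return _correlations(w)
    if extractor == "time_magnitude":
        return _time_domain(np.linalg.norm(w, axis=1), "mag")
    raise KeyError(f"unknown feature extractor {extractor!r}")


def extract_features(ws: WindowSet, bank: list[str] | None = None) -> FeatureTable:
    """Compute the per-window feature matrix (unstandardized).

    ``bank`` is an ordered list of extractor names; defaults to
    :func:`default_feature_bank`.  Any NaN raises an error naming the
    offending feature and window.
    """
    if len(ws) == 0:
        raise EmptyInputError("no windows to extract features from")
    bank = list(bank) if bank is not None else default_feature_bank()
    rows: list[list[float]] = []
    names: list[str] | None = None
    for wi, w in enumerate(ws.windows):
        feats: dict[str, float] = {}
        for extractor in bank:
            feats.update(_extract_one(w, ws.sampling_rate, extractor))
        if names is None:
            names = list(feats)
        row = [feats[k] for k in names]
        for k, v in feats.items():
            if not np.isfinite(v):
                raise ValueError(f"feature {k!r} is not finite for window {wi}")
        rows.append(row)
    X = np.asarray(rows, dtype=float)
    cfg = json.dumps({"bank": bank, "bands": DEFAULT_BANDS}, default=list)
    meta = {
        "bank": bank,
        "config_hash": hashlib.sha256(cfg.encode()).hexdigest()[:12],
        "sampling_rate": ws.sampling_rate,
    }
    return FeatureTable(
        X=X,
        feature_names=list(names or []),
        labels=list(ws.labels),
        subject_id=ws.subject_id,
        standardized=False,
        meta=meta,
    )


def standardize(ft: FeatureTable) -> FeatureTable:
    """Column-wise z-scoring (sample s.d., n−1) on the subject's own data.

    Constant columns are set to 0 and flagged so they cannot propagate NaN
    into the embedding.
    """
    if ft.n_windows < 2:
        raise EmptyInputError("need at least 2 windows to standardize")
    mu = ft.X.mean(axis=0)
    sd = ft.X.std(axis=0, ddof=1)
    constant = sd < 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    Z = (ft.X - mu) / sd_safe
    Z[:, constant] = 0.0
    return FeatureTable(
        X=Z,
        feature_names=list(ft.feature_names),
        labels=list(ft.labels),
        subject_id=ft.subject_id,
        standardized=True,
        constant_columns=[ft.feature_names[i] for i in np.nonzero(constant)[0]],
        meta=dict(ft.meta),
    )
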