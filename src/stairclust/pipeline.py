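"""End-to-end per-subject pipeline: recording -> features -> evaluation."""

from __future__ import annotations

from dataclasses import dataclass

from stairclust.embedding import TSNEParams
from stairclust.evaluation import DEFAULT_SEEDS, EvalReport, evaluate_subject
from stairclust.features import (
    FeatureTable,
    bandpass_filter,
    extract_features,
    segment_windows,
    standardize,
)
from stairclust.ingest import LabelTrack, Recording, ResolutionLevel


@dataclass
class PipelineConfig:
    """Tunable parameters of the per-subject pipeline."""

    window_len: float = 2.0
    band_low: float = 0.4
    band_high: float = 3.0
    resolution_level: ResolutionLevel = ResolutionLevel.LEVEL0
    eps: float = 3.0
    min_points: int = 15
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    tsne: TSNEParams = TSNEParams()


def build_features(
    rec: Recording, track: LabelTrack, config: PipelineConfig | None = None
) -> FeatureTable:
    """Filter, window, extract and standardize one subject's features."""
    config = config or PipelineConfig()
    filtered = bandpass_filter(rec, config.band_low, config.band_high)
    ws = segment_windows(filtered, track, config.window_len, config.resolution_level)
    return standardize(extract_features(ws))


def run_subject(
    rec: Recording, track: LabelTrack, config: PipelineConfig | None = None
) -> EvalReport:
    """Full pipeline for one subject across the configured seeds."""
    config = config or PipelineConfig()
    ft = build_features(rec, track, config)
    return evaluate_subject(
        ft,
        seeds=config.seeds,
        params=config.tsne,
        eps=config.eps,
        min_points=config.min_points,
    )
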