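"""End-to-end convenience: detect -> classify -> score (-> heterogeneity).

These functions are what the CLI's ``pipeline`` subcommand calls; tests and
scripts use them directly.
"""
from __future__ import annotations

from dataclasses import dataclass

from .classification import SignalClassifier, classify_signals
from .detection import DetectionParams, detect_signals, detect_signals_tiled
from .points import SignalPoint
from .raster import RasterImage, TissueMask, compute_tissue_mask
from .scoring import (
    GeneStatus,
    MixedPolicy,
    RatioScore,
    ThresholdConfig,
    call_status,
    global_ratio,
)


@dataclass
class CoreResult:
    points: list[SignalPoint]
    score: RatioScore
    status: GeneStatus | None
    threshold: ThresholdConfig

    @property
    def ratio(self) -> float | None:
        return self.score.global_ratio


def analyze_core(
    image: RasterImage,
    classifier: SignalClassifier,
    mask: TissueMask | None = None,
    detection: DetectionParams | None = None,
    thresholds: ThresholdConfig | None = None,
    policy: MixedPolicy = MixedPolicy.COUNT_BOTH,
    compute_mask: bool = True,
) -> CoreResult:
    """Detect, classify and score one preprocessed core image."""
    thresholds = thresholds or ThresholdConfig()
    if mask is None and compute_mask:
        mask = compute_tissue_mask(image)
    detected = detect_signals(image, mask, detection)
    labeled = classify_signals(classifier, image, detected)
    score = global_ratio(labeled, policy)
    status = None
    if score.global_ratio is not None:
        status = call_status(score, thresholds)
    return CoreResult(points=labeled, score=score, status=status, threshold=thresholds)


def analyze_slide(
    image: RasterImage,
    classifier: SignalClassifier,
    detection: DetectionParams | None = None,
    tile_size: int = 4096,
    overlap: int = 64,
    thresholds: ThresholdConfig | None = None,
    policy: MixedPolicy = MixedPolicy.COUNT_BOTH,
) -> CoreResult:
    """Tiled whole-slide variant: per-tile detection merged in global
    coordinates, then one classification and scoring pass."""
    thresholds = thresholds or ThresholdConfig()
    detected = detect_signals_tiled(image, None, detection, tile_size, overlap)
    labeled = classify_signals(classifier, image, detected)
    score = global_ratio(labeled, policy)
    status = None
    if score.global_ratio is not None:
        status = call_status(score, thresholds)
    return CoreResult(points=labeled, score=score, status=status, threshold=thresholds)
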