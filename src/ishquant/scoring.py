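"""Region-based copy-number scoring.

The global ratio of a tissue region is (all gene signals) / (all CEP
signals) — no nucleus segmentation involved.  A colocalized mixed signal
contains one gene and one CEP dot, so by default it adds one to each count
(``count_both``); ``exclude`` drops mixed signals entirely and is offered
for sensitivity analysis.  Status calls are a step function of the ratio:
for a deletion assay, ratio <= 0.60 calls DELETION (boundary inclusive);
for an amplification assay, ratio >= 2.0 calls AMPLIFICATION.

``roc_analysis`` reproduces how a threshold is tuned against a manual
reference standard: global ratios act as prediction scores, AUC comes from
the trapezoidal ROC area (identical to the Mann-Whitney rank statistic),
the 95% CI from 1,000 case-resampled bootstrap replicates, and the
operating point from Youden's J (equal-cost slope criterion) or the
closest-to-(0,1) rule.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, ParameterError
from .points import SignalLabel, SignalPoint

DELETION_THRESHOLD = 0.60
AMPLIFICATION_THRESHOLD = 2.0


class MixedPolicy(str, enum.Enum):
    COUNT_BOTH = "count_both"
    EXCLUDE = "exclude"


class GeneStatus(str, enum.Enum):
    DELETION = "DELETION"
    NORMAL = "NORMAL"
    AMPLIFICATION = "AMPLIFICATION"


@dataclass(frozen=True)
class RatioScore:
    gene_count: int
    cep_count: int
    mixed_count: int
    mixed_policy: MixedPolicy = MixedPolicy.COUNT_BOTH

    @property
    def effective_gene(self) -> int:
        if self.mixed_policy is MixedPolicy.COUNT_BOTH:
            return self.gene_count + self.mixed_count
        return self.gene_count

    @property
    def effective_cep(self) -> int:
        if self.mixed_policy is MixedPolicy.COUNT_BOTH:
            return self.cep_count + self.mixed_count
        return self.cep_count

    @property
    def global_ratio(self) -> float | None:
        """None iff the (policy-adjusted) CEP denominator is zero."""
        den = self.effective_cep
        if den == 0:
            return None
        return self.effective_gene / den


@dataclass(frozen=True)
class ThresholdConfig:
    deletion_threshold: float = DELETION_THRESHOLD
    amplification_threshold: float = AMPLIFICATION_THRESHOLD
    direction: str = "deletion_assay"  # deletion_assay | amplification_assay

    def __post_init__(self):
        if self.deletion_threshold >= self.amplification_threshold:
            raise ParameterError(
                "deletion_threshold must be below amplification_threshold"
            )
        if self.direction not in ("deletion_assay", "amplification_assay"):
            raise ParameterError(f"unknown direction {self.direction!r}")


def global_ratio(
    points: Sequence[SignalPoint],
    policy: MixedPolicy | str = MixedPolicy.COUNT_BOTH,
) -> RatioScore:
    """Tally GENE / CEP / MIXED labels; NOISE and CELL_STAIN never count."""
    policy = MixedPolicy(policy)
    gene = cep = mixed = 0
    for p in points:
        if p.label is SignalLabel.GENE:
            gene += 1
        elif p.label is SignalLabel.CEP:
            cep += 1
        elif p.label is SignalLabel.GENE_CEP_MIXED:
            mixed += 1
    return RatioScore(gene_count=gene, cep_count=cep, mixed_count=mixed, mixed_policy=policy)


def call_status(score: RatioScore | float, config: ThresholdConfig | None = None) -> GeneStatus:
    """Dichotomize a defined ratio against the configured threshold."""
    config = config or ThresholdConfig()
    ratio = score.global_ratio if isinstance(score, RatioScore) else float(score)
    if ratio is None:
        raise AnalysisError("global ratio undefined (zero CEP denominator): no status call")
    if config.direction == "deletion_assay":
        return GeneStatus.DELETION if ratio <= config.deletion_threshold else GeneStatus.NORMAL
    return (
        GeneStatus.AMPLIFICATION
        if ratio >= config.amplification_threshold
        else GeneStatus.NORMAL
    )


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    optimal_threshold: float
    accuracy_at_threshold: float
    curve: np.ndarray  # (n, 3): fpr, tpr, threshold

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "optimal_threshold": self.optimal_threshold,
            "accuracy_at_threshold": self.accuracy_at_threshold,
        }


def _auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return area, np.column_stack([fpr, tpr, thr])


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
    criterion: str = "youden",
) -> ROCResult:
    """ROC of ``scores`` against binary ``labels`` (1 = positive, and a
    higher score means more positive).

    AUC is the trapezoidal area under the empirical curve; its 95% CI is the
    percentile interval over ``n_boot`` case-resampled bootstrap replicates
    (replicates that lose one class are redrawn).  The operating threshold
    maximizes Youden's J = TPR - FPR, or minimizes distance to (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise AnalysisError("scores and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise AnalysisError("ROC needs both label values present")
    if criterion not in ("youden", "closest_topleft"):
        raise ParameterError(f"unknown criterion {criterion!r}")

    area, curve = _auc(scores, labels)
    fpr, tpr, thr = curve.T
    if criterion == "youden":
        best = int(np.argmax(tpr - fpr))
    else:
        best = int(np.argmin(fpr**2 + (1.0 - tpr) ** 2))
    threshold = float(thr[best])
    pred = scores >= threshold
    accuracy = float((pred == (labels == 1)).mean())

    rng = np.random.default_rng(seed)
    n = len(scores)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        boot[b], _ = _auc(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(
        auc=area,
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        optimal_threshold=threshold,
        accuracy_at_threshold=accuracy,
        curve=curve,
    )
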