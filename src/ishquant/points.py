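"""Signal points: the unit record of the whole pipeline.

A *signal point* is one detected (or planted) circular ISH dot: a silver
gene dot, a red centromere (CEP) dot, a colocalized gene+CEP pair, a piece
of background debris, or a spot inside a diffuse cell stain.  Point sets
move between modules as lists of :class:`SignalPoint` and are serialized as
plain CSV with one row per signal.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SignalLabel(str, enum.Enum):
    """The five signal classes assigned by the classifier.

    GENE / CEP are probe-agnostic: the same vocabulary serves PTEN/CEP10,
    19q12/CEP19 or HER2/CEP17 assays.
    """

    GENE = "GENE"
    CEP = "CEP"
    GENE_CEP_MIXED = "GENE_CEP_MIXED"
    NOISE = "NOISE"
    CELL_STAIN = "CELL_STAIN"


#: Labels that enter ratio scoring (NOISE and CELL_STAIN never do).
SCORED_LABELS = (SignalLabel.GENE, SignalLabel.CEP, SignalLabel.GENE_CEP_MIXED)


@dataclass(frozen=True)
class SignalPoint:
    """One circular signal.

    Coordinates are 0-based pixels, ``x`` = column (rightward), ``y`` = row
    (downward).  ``strength`` is the detector's accumulator value (0 for
    planted ground-truth points).  ``label``/``label_score`` are filled by
    the classifier.
    """

    x: float
    y: float
    radius: float
    strength: float = 0.0
    label: SignalLabel | None = None
    label_score: float | None = None

    def with_label(self, label: SignalLabel, score: float) -> "SignalPoint":
        return replace(self, label=label, label_score=float(score))

    def shifted(self, dx: float, dy: float) -> "SignalPoint":
        return replace(self, x=self.x + dx, y=self.y + dy)


# ---------------------------------------------------------------------------
# array / frame conversions

def points_to_arrays(points: Sequence[SignalPoint]) -> dict[str, np.ndarray]:
    """Columnar view of a point list (empty-safe)."""
    return {
        "x": np.array([p.x for p in points], dtype=float),
        "y": np.array([p.y for p in points], dtype=float),
        "radius": np.array([p.radius for p in points], dtype=float),
        "strength": np.array([p.strength for p in points], dtype=float),
        "label": np.array(
            [p.label.value if p.label is not None else "" for p in points],
            dtype=object,
        ),
        "label_score": np.array(
            [np.nan if p.label_score is None else p.label_score for p in points],
            dtype=float,
        ),
    }


def points_to_frame(points: Sequence[SignalPoint]) -> pd.DataFrame:
    return pd.DataFrame(points_to_arrays(points))


def frame_to_points(df: pd.DataFrame) -> list[SignalPoint]:
    pts = []
    has_label = "label" in df.columns
    has_score = "label_score" in df.columns
    for row in df.itertuples(index=False):
        label = None
        score = None
        if has_label:
            raw = getattr(row, "label")
            if isinstance(raw, str) and raw:
                label = SignalLabel(raw)
        if has_score:
            s = getattr(row, "label_score")
            if s is not None and np.isfinite(s):
                score = float(s)
        pts.append(
            SignalPoint(
                x=float(row.x),
                y=float(row.y),
                radius=float(row.radius),
                strength=float(getattr(row, "strength", 0.0)),
                label=label,
                label_score=score,
            )
        )
    return pts


def write_points_csv(points: Sequence[SignalPoint], path) -> None:
    """One row per signal, header required; stable float formatting so that
    seeded reruns are byte-identical."""
    points_to_frame(points).to_csv(path, index=False, float_format="%.6f")


def read_points_csv(path) -> list[SignalPoint]:
    return frame_to_points(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def coords(points: Iterable[SignalPoint]) -> np.ndarray:
    """(n, 2) array of (x, y)."""
    arr = np.array([(p.x, p.y) for p in points], dtype=float)
    return arr.reshape(-1, 2)


def select_labels(points: Sequence[SignalPoint], labels) -> list[SignalPoint]:
    wanted = set(labels)
    return [p for p in points if p.label in wanted]
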