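"""Signal colour maps, local-ratio bar grids, and embedding figures.

Every figure gets a machine-readable sidecar (CSV/JSON) so downstream
checks read data, not pixels.  The whole-slide "3-D bar graph" of local
ratios is delivered as a heat map plus its exported matrix — the 3-D
perspective is cosmetic, the matrix is the content.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .heterogeneity import EmbeddingResult, MixtureModel, PerturbationEllipse
from .points import SignalLabel, SignalPoint
from .raster import RasterImage
from .scoring import MixedPolicy


@dataclass(frozen=True)
class ColourMapStyle:
    """Canonical palette: black gene, red CEP, green colocalized."""

    gene_colour: tuple[int, int, int] = (0, 0, 0)
    cep_colour: tuple[int, int, int] = (255, 0, 0)
    mixed_colour: tuple[int, int, int] = (0, 170, 0)
    glyph_size: int = 5  # square side in px
    background: str = "white"  # white | dimmed_tissue

    def __post_init__(self):
        if len({self.gene_colour, self.cep_colour, self.mixed_colour}) != 3:
            raise ParameterError("gene/cep/mixed colours must be distinct")
        if self.glyph_size < 1:
            raise ParameterError("glyph_size must be >= 1")


@dataclass
class BarGridResult:
    grid: np.ndarray  # local ratio per tile, NaN where undefined
    tile_size: int
    min_cep_per_tile: int
    gene_counts: np.ndarray
    cep_counts: np.ndarray
    mixed_counts: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ny, nx = self.grid.shape
        for iy in range(ny):
            for ix in range(nx):
                rows.append(
                    dict(
                        tile_x=ix,
                        tile_y=iy,
                        gene=int(self.gene_counts[iy, ix]),
                        cep=int(self.cep_counts[iy, ix]),
                        mixed=int(self.mixed_counts[iy, ix]),
                        ratio=self.grid[iy, ix],
                    )
                )
        return pd.DataFrame(rows)


def render_colour_map(
    points: Sequence[SignalPoint],
    canvas: tuple[int, int],
    style: ColourMapStyle | None = None,
    tissue: RasterImage | None = None,
) -> RasterImage:
    """One square glyph per GENE/CEP/MIXED point at its own coordinates
    (geometry preserved — no rescaling); NOISE and CELL_STAIN are omitted."""
    style = style or ColourMapStyle()
    h, w = canvas
    if style.background == "dimmed_tissue" and tissue is not None:
        img = (tissue.pixels.astype(np.float32) * 0.35 + 255 * 0.65).astype(np.uint8)
    else:
        img = np.full((h, w, 3), 255, dtype=np.uint8)
    palette = {
        SignalLabel.GENE: style.gene_colour,
        SignalLabel.CEP: style.cep_colour,
        SignalLabel.GENE_CEP_MIXED: style.mixed_colour,
    }
    half = style.glyph_size // 2
    # draw mixed last so colocalized evidence stays visible over dense dots
    order = (SignalLabel.GENE, SignalLabel.CEP, SignalLabel.GENE_CEP_MIXED)
    for label in order:
        colour = palette[label]
        for p in points:
            if p.label is not label:
                continue
            x, y = int(round(p.x)), int(round(p.y))
            x0, x1 = max(0, x - half), min(w, x - half + style.glyph_size)
            y0, y1 = max(0, y - half), min(h, y - half + style.glyph_size)
            if x0 < x1 and y0 < y1:
                img[y0:y1, x0:x1] = colour
    return RasterImage(img)


def compute_bar_grid(
    points: Sequence[SignalPoint],
    canvas: tuple[int, int],
    tile_size: int,
    min_cep: int = 5,
    policy: MixedPolicy = MixedPolicy.COUNT_BOTH,
) -> BarGridResult:
    """Local gene:CEP ratio per fixed square tile.

    Each tile's ratio is the scoring module's global ratio restricted to the
    tile; tiles whose (policy-adjusted) CEP count falls below ``min_cep``
    are undefined (NaN).  Summing the per-tile counts recovers the
    whole-image counts exactly.
    """
    if tile_size < 32:
        raise ParameterError("tile_size must be >= 32")
    h, w = canvas
    ny = int(np.ceil(h / tile_size))
    nx = int(np.ceil(w / tile_size))
    gene = np.zeros((ny, nx), dtype=int)
    cep = np.zeros((ny, nx), dtype=int)
    mixed = np.zeros((ny, nx), dtype=int)
    for p in points:
        ix = int(p.x // tile_size)
        iy = int(p.y // tile_size)
        if not (0 <= ix < nx and 0 <= iy < ny):
            continue
        if p.label is SignalLabel.GENE:
            gene[iy, ix] += 1
        elif p.label is SignalLabel.CEP:
            cep[iy, ix] += 1
        elif p.label is SignalLabel.GENE_CEP_MIXED:
            mixed[iy, ix] += 1
    if policy is MixedPolicy.COUNT_BOTH:
        eff_gene = gene + mixed
        eff_cep = cep + mixed
    else:
        eff_gene = gene
        eff_cep = cep
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = np.where(eff_cep >= max(min_cep, 1), eff_gene / np.maximum(eff_cep, 1), np.nan)
    return BarGridResult(
        grid=grid,
        tile_size=tile_size,
        min_cep_per_tile=min_cep,
        gene_counts=gene,
        cep_counts=cep,
        mixed_counts=mixed,
    )


def render_bar_grid(result: BarGridResult, path, cmap: str = "RdBu_r") -> None:
    """Heat map of the local-ratio grid + CSV sidecar next to it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(result.grid, cmap=cmap, vmin=0.0, vmax=2.0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="local gene:CEP ratio")
    ax.set_xlabel("tile x")
    ax.set_ylabel("tile y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    result.to_frame().to_csv(path.with_suffix(".csv"), index=False, float_format="%.6f")


def render_embedding(
    embedding: EmbeddingResult,
    model: MixtureModel,
    path,
    ellipses: Sequence[PerturbationEllipse] | None = None,
    distances: Sequence[float] | None = None,
    core_ids: Sequence | None = None,
) -> None:
    """Cohort scatter in PC space: points coloured by cluster, centroids
    starred, optional robustness ellipses and per-core Mahalanobis
    annotations; a JSON sidecar carries everything machine-readable."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    path = Path(path)
    coords = embedding.coords
    n = len(coords)
    if len(model.assignments) != n:
        raise ParameterError("model assignments and embedding coords disagree in length")
    if distances is not None and len(distances) != n:
        raise ParameterError("distances and coords disagree in length")
    if ellipses is not None and len(ellipses) != n:
        raise ParameterError("ellipses and coords disagree in length")

    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for comp in range(model.k):
        sel = model.assignments == comp
        ax.scatter(
            coords[sel, 0], coords[sel, 1], s=30, color=cmap(comp % 10),
            label=f"cluster {comp}", zorder=3,
        )
    ax.scatter(
        model.means[:, 0], model.means[:, 1], marker="*", s=260, color="black",
        zorder=4, label="centroids",
    )
    if ellipses is not None:
        for e, comp in zip(ellipses, model.assignments):
            ax.add_patch(
                MplEllipse(
                    xy=e.center, width=2 * e.axes[0], height=2 * e.axes[1],
                    angle=np.degrees(e.orientation), fill=False,
                    edgecolor=cmap(int(comp) % 10), lw=0.8, zorder=2,
                )
            )
    if distances is not None:
        for (x, y), d in zip(coords, distances):
            ax.annotate(f"{d:.1f}", (x, y), fontsize=6, xytext=(3, 3),
                        textcoords="offset points")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    sidecar = {
        "core_ids": list(core_ids) if core_ids is not None else list(range(n)),
        "pc1": coords[:, 0].tolist(),
        "pc2": coords[:, 1].tolist(),
        "cluster": model.assignments.tolist(),
        "k": model.k,
        "centroids": model.means.tolist(),
        "explained_variance": embedding.explained_variance.tolist(),
        "mahalanobis": list(map(float, distances)) if distances is not None else None,
        "ellipses": [
            {
                "center": e.center.tolist(),
                "axes": list(e.axes),
                "orientation": e.orientation,
                "n_reps": e.n_reps,
            }
            for e in ellipses
        ]
        if ellipses is not None
        else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
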