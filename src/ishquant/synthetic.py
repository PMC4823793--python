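"""Synthetic DISH cores with planted ground truth.

The generator emulates what a dual-colour chromogenic/silver ISH core looks
like at the 4096 x 4096 working scale: tumour cells scattered by a
hard-core point process inside a circular tissue region on a pale
hematoxylin-like background, each cell shedding a small number of
near-black gene dots and red centromere (CEP) dots, a fraction of which
colocalize into mixed gene+CEP signals; plus brownish background debris
("noise") and large diffuse bluish cell stains.  Sectioning truncation is
modelled as an equal-channel Bernoulli signal loss, which leaves the
expected gene:CEP ratio unchanged — the property that makes region-based
ratio scoring robust to cutting artifacts.

Six prototypes cover the canonical genotype/heterogeneity configurations:

=============================================  ==========================================
prototype                                      construction
=============================================  ==========================================
HOMOZYGOUS_DELETION                            central blob with 0 gene copies, thin
                                               benign rim keeping 2 (residual normal
                                               epithelium survives in real sections)
HEMIZYGOUS_DELETION                            1 gene copy everywhere
NON_DELETION                                   2 gene copies everywhere
CELLULAR_HET_HOMOGENEOUS_GENOTYPE              2 copies everywhere, clustered cell
                                               density (varying tissue composition)
CELLULAR_HET_HETEROGENEOUS_GENOTYPE            deleted blob + normal surround, clustered
                                               cell density
INTRATUMOUR_HET                                half-plane split: one side 2 copies,
                                               the other 0
=============================================  ==========================================

Every generated object carries its full ground truth (true signal table,
planted per-region ratios, expected global ratio) so that detection,
classification, scoring and heterogeneity statistics can each be graded
against what was actually planted.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .points import SignalLabel, SignalPoint
from .raster import RasterImage, TissueMask

import enum


class CorePrototype(str, enum.Enum):
    HOMOZYGOUS_DELETION = "HOMOZYGOUS_DELETION"
    HEMIZYGOUS_DELETION = "HEMIZYGOUS_DELETION"
    NON_DELETION = "NON_DELETION"
    CELLULAR_HET_HOMOGENEOUS_GENOTYPE = "CELLULAR_HET_HOMOGENEOUS_GENOTYPE"
    CELLULAR_HET_HETEROGENEOUS_GENOTYPE = "CELLULAR_HET_HETEROGENEOUS_GENOTYPE"
    INTRATUMOUR_HET = "INTRATUMOUR_HET"


#: prototypes whose gene:CEP ratio is spatially uniform
HOMOGENEOUS_PROTOTYPES = (
    CorePrototype.HEMIZYGOUS_DELETION,
    CorePrototype.NON_DELETION,
    CorePrototype.CELLULAR_HET_HOMOGENEOUS_GENOTYPE,
)
#: prototypes with genuine spatial variation of genotype
HETEROGENEOUS_PROTOTYPES = (
    CorePrototype.CELLULAR_HET_HETEROGENEOUS_GENOTYPE,
    CorePrototype.INTRATUMOUR_HET,
)


@dataclass(frozen=True)
class DiskMask:
    """Analytic circular tissue region (cheap stand-in for a raster mask)."""

    cx: float
    cy: float
    r: float
    canvas: tuple[int, int] = (4096, 4096)  # (height, width)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        h, w = self.canvas
        return (
            max(0, int(self.cx - self.r)),
            max(0, int(self.cy - self.r)),
            min(w, int(np.ceil(self.cx + self.r)) + 1),
            min(h, int(np.ceil(self.cy + self.r)) + 1),
        )

    def rasterize(self) -> TissueMask:
        h, w = self.canvas
        yy, xx = np.ogrid[:h, :w]
        return TissueMask((xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.r**2)


@dataclass
class SyntheticCoreSpec:
    """Full recipe for one synthetic core.

    Densities are per-pixel-squared rates over the tissue disk.  Defaults
    yield roughly 3,000-3,500 plantable dot signals per core — inside the
    1,000-5,000 band typical for one tissue core — of which roughly 30%
    are gene/CEP signals, the rest debris and stain hits.
    """

    prototype: CorePrototype = CorePrototype.NON_DELETION
    n_cells: int = 330
    gene_copies_per_region: tuple[int, ...] = (2,)
    cep_copies: int = 2
    region_geometry: str = "whole"  # whole | half_plane | blob
    signal_loss_prob: float = 0.15
    colocalization_prob: float = 0.08
    noise_density: float = 2.4e-3
    stain_density: float = 3.0e-5
    dot_radius_range: tuple[float, float] = (3.5, 5.5)
    seed: int = 0
    # geometry / texture knobs
    canvas_size: int = 4096
    core_radius: float = 560.0
    cell_radius: float = 14.0
    cell_min_distance: float = 42.0
    signal_min_distance: float = 9.0
    blob_radius_fraction: float = 0.9
    density_field: str = "uniform"  # uniform | clustered
    noise_radius_range: tuple[float, float] = (3.0, 4.5)
    stain_radius_range: tuple[float, float] = (18.0, 30.0)

    def __post_init__(self):
        n_regions = {"whole": 1, "half_plane": 2, "blob": 2}.get(self.region_geometry)
        if n_regions is None:
            raise ParameterError(f"unknown region_geometry {self.region_geometry!r}")
        if len(self.gene_copies_per_region) != n_regions:
            raise ParameterError(
                f"{self.region_geometry!r} geometry needs {n_regions} gene-copy "
                f"entries, got {len(self.gene_copies_per_region)}"
            )
        for p in (self.signal_loss_prob, self.colocalization_prob):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("probabilities must be in [0, 1]")
        if self.density_field not in ("uniform", "clustered"):
            raise ParameterError(f"unknown density_field {self.density_field!r}")

    def replace(self, **kw) -> "SyntheticCoreSpec":
        return _dc_replace(self, **kw)


_PROTOTYPE_DEFAULTS: dict[CorePrototype, dict] = {
    CorePrototype.HOMOZYGOUS_DELETION: dict(
        region_geometry="blob", gene_copies_per_region=(0, 2), blob_radius_fraction=0.9
    ),
    CorePrototype.HEMIZYGOUS_DELETION: dict(
        region_geometry="whole", gene_copies_per_region=(1,)
    ),
    CorePrototype.NON_DELETION: dict(
        region_geometry="whole", gene_copies_per_region=(2,)
    ),
    CorePrototype.CELLULAR_HET_HOMOGENEOUS_GENOTYPE: dict(
        region_geometry="whole", gene_copies_per_region=(2,), density_field="clustered"
    ),
    CorePrototype.CELLULAR_HET_HETEROGENEOUS_GENOTYPE: dict(
        region_geometry="blob",
        gene_copies_per_region=(0, 2),
        blob_radius_fraction=0.6,
        density_field="clustered",
    ),
    CorePrototype.INTRATUMOUR_HET: dict(
        region_geometry="half_plane", gene_copies_per_region=(2, 0)
    ),
}


def spec_for_prototype(prototype: CorePrototype | str, seed: int = 0, **overrides) -> SyntheticCoreSpec:
    """Canonical spec for one of the six prototypes (overrides win)."""
    prototype = CorePrototype(prototype)
    kw = dict(_PROTOTYPE_DEFAULTS[prototype])
    kw.update(overrides)
    return SyntheticCoreSpec(prototype=prototype, seed=seed, **kw)


@dataclass
class GroundTruth:
    """Everything that was planted, for grading the pipeline against."""

    points: list[SignalPoint]
    frame: pd.DataFrame  # x, y, radius, true_label, region_id
    mask: DiskMask
    expected_global_ratio: float
    region_table: pd.DataFrame  # region_id, gene_copies, planted_ratio, n_cells
    spec: SyntheticCoreSpec

    def shifted(self, dx: float, dy: float) -> "GroundTruth":
        frame = self.frame.copy()
        frame["x"] += dx
        frame["y"] += dy
        mask = DiskMask(self.mask.cx + dx, self.mask.cy + dy, self.mask.r, self.mask.canvas)
        return GroundTruth(
            points=[p.shifted(dx, dy) for p in self.points],
            frame=frame,
            mask=mask,
            expected_global_ratio=self.expected_global_ratio,
            region_table=self.region_table,
            spec=self.spec,
        )


# ---------------------------------------------------------------------------
# geometry helpers

def _region_of(x, y, spec: SyntheticCoreSpec, cx: float, cy: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.region_geometry == "whole":
        return np.zeros(x.shape, dtype=int)
    if spec.region_geometry == "half_plane":
        return (x >= cx).astype(int)
    # blob: region 0 = central disk
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= (spec.blob_radius_fraction * spec.core_radius) ** 2
    return (~inside).astype(int)


class _GridHash:
    """Uniform-grid nearest-point rejection for hard-core sampling."""

    def __init__(self, cell: float):
        self.cell = cell
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(self, x: float, y: float, min_dist: float) -> bool:
        gx, gy = int(x // self.cell), int(y // self.cell)
        reach = int(np.ceil(min_dist / self.cell))
        m2 = min_dist * min_dist
        for iy in range(gy - reach, gy + reach + 1):
            for ix in range(gx - reach, gx + reach + 1):
                for (px, py) in self.grid.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < m2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.grid.setdefault((int(x // self.cell), int(y // self.cell)), []).append((x, y))


def _place_cells(spec: SyntheticCoreSpec, rng: np.random.Generator, cx: float, cy: float):
    """Hard-core cell placement, optionally thinned by a clustered intensity."""
    R = spec.core_radius
    if spec.density_field == "clustered":
        k = 4
        ang = rng.uniform(0, 2 * np.pi, k)
        rad = R * np.sqrt(rng.uniform(0.05, 0.8, k))
        centers = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        sigma = R / 4.0
    grid = _GridHash(max(spec.cell_min_distance, 1.0))
    pts = []
    attempts = 0
    max_attempts = 400 * spec.n_cells
    while len(pts) < spec.n_cells and attempts < max_attempts:
        attempts += 1
        r = R * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        x, y = cx + r * np.cos(a), cy + r * np.sin(a)
        if spec.density_field == "clustered":
            d2 = ((centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2) / (2 * sigma**2)
            intensity = 0.15 + 0.85 * np.exp(-d2).max()
            if rng.uniform() > intensity:
                continue
        if not grid.ok(x, y, spec.cell_min_distance):
            continue
        grid.add(x, y)
        pts.append((x, y))
    if len(pts) < spec.n_cells:
        raise GenerationError(
            f"could not place {spec.n_cells} cells at min distance "
            f"{spec.cell_min_distance} inside radius {R}: packing infeasible"
        )
    return np.asarray(pts)


def _jitter_in_cell(
    rng: np.random.Generator, cx: float, cy: float, n: int, spec: SyntheticCoreSpec, occupied: _GridHash
):
    """Place n signal points inside one cell, keeping signals apart so that
    neighbouring dots remain individually resolvable."""
    out = []
    for _ in range(n):
        placed = None
        for _try in range(40):
            r = spec.cell_radius * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(a), cy + r * np.sin(a)
            if occupied.ok(x, y, spec.signal_min_distance):
                placed = (x, y)
                break
        if placed is None:  # crowded cell: accept the last candidate
            placed = (x, y)
        occupied.add(*placed)
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# operations

def generate_point_set(spec: SyntheticCoreSpec) -> GroundTruth:
    """Plant the true signal table for one core (no rendering).

    Each cell emits Binomial(cep_copies, 1 - loss) CEP dots and
    Binomial(region gene copies, 1 - loss) gene dots jittered within the
    cell radius; per cell, min(gene, cep) candidate pairs each colocalize
    into one GENE_CEP_MIXED dot with ``colocalization_prob``.  Debris and
    stains are added at their per-area densities.  The expected global
    ratio is the exact conditional expectation given the cell placement:
    mean planted gene copies per cell / cep_copies — independent of the
    (equal-channel) loss and colocalization probabilities.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    half = spec.canvas_size / 2.0
    cx = cy = half
    mask = DiskMask(cx, cy, spec.core_radius, (spec.canvas_size, spec.canvas_size))

    cells = _place_cells(spec, rng, cx, cy)
    regions = _region_of(cells[:, 0], cells[:, 1], spec, cx, cy)
    gene_copies = np.asarray(spec.gene_copies_per_region, dtype=int)[regions]

    occupied = _GridHash(max(spec.signal_min_distance, 1.0))
    rows = []  # (x, y, radius, label, region_id)
    rmin, rmax = spec.dot_radius_range
    keep = 1.0 - spec.signal_loss_prob
    for (px, py), region, g in zip(cells, regions, gene_copies):
        n_cep = rng.binomial(spec.cep_copies, keep)
        n_gene = rng.binomial(int(g), keep)
        n_mix = rng.binomial(min(n_cep, n_gene), spec.colocalization_prob) if min(n_cep, n_gene) else 0
        n_cep -= n_mix
        n_gene -= n_mix
        counts = (
            (SignalLabel.GENE, n_gene),
            (SignalLabel.CEP, n_cep),
            (SignalLabel.GENE_CEP_MIXED, n_mix),
        )
        for label, n in counts:
            for (x, y) in _jitter_in_cell(rng, px, py, n, spec, occupied):
                rows.append((x, y, rng.uniform(rmin, rmax), label, region))

    area = np.pi * spec.core_radius**2
    n_noise = rng.poisson(spec.noise_density * area)
    n_stain = rng.poisson(spec.stain_density * area)
    nrmin, nrmax = spec.noise_radius_range
    srmin, srmax = spec.stain_radius_range
    for label, n, lo, hi, min_d in (
        (SignalLabel.NOISE, n_noise, nrmin, nrmax, spec.signal_min_distance),
        (SignalLabel.CELL_STAIN, n_stain, srmin, srmax, 2.0 * srmax),
    ):
        placed = 0
        attempts = 0
        while placed < n and attempts < 60 * max(n, 1):
            attempts += 1
            r = spec.core_radius * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(a), cy + r * np.sin(a)
            if not occupied.ok(x, y, min_d):
                continue
            occupied.add(x, y)
            rows.append((x, y, rng.uniform(lo, hi), label, -1))
            placed += 1

    frame = pd.DataFrame(rows, columns=["x", "y", "radius", "true_label", "region_id"])
    frame["true_label"] = frame["true_label"].map(lambda l: l.value)
    points = [
        SignalPoint(x=r.x, y=r.y, radius=r.radius, label=SignalLabel(r.true_label))
        for r in frame.itertuples(index=False)
    ]

    if spec.cep_copies > 0:
        expected_ratio = float(gene_copies.mean() / spec.cep_copies)
    else:
        expected_ratio = float("nan")  # no denominator channel planted
    region_rows = []
    for rid in sorted(set(regions.tolist())):
        g = int(np.asarray(spec.gene_copies_per_region)[rid])
        region_rows.append(
            dict(
                region_id=rid,
                gene_copies=g,
                planted_ratio=g / spec.cep_copies if spec.cep_copies > 0 else float("nan"),
                n_cells=int((regions == rid).sum()),
            )
        )
    return GroundTruth(
        points=points,
        frame=frame,
        mask=mask,
        expected_global_ratio=expected_ratio,
        region_table=pd.DataFrame(region_rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# rendering

_BACKGROUND_RGB = np.array([0.91, 0.88, 0.93], dtype=np.float32)  # pale hematoxylin
_GENE_RGB = np.array([0.08, 0.07, 0.06], dtype=np.float32)  # silver/black
_CEP_RGB = np.array([0.72, 0.12, 0.10], dtype=np.float32)  # chromogenic red
_NOISE_RGB = np.array([0.55, 0.50, 0.46], dtype=np.float32)  # brownish debris
_STAIN_RGB = np.array([0.60, 0.58, 0.78], dtype=np.float32)  # diffuse bluish stain


def _paint_disk(canvas: np.ndarray, x: float, y: float, r: float, rgb: np.ndarray,
                softness: float = 0.75, alpha_max: float = 1.0) -> None:
    h, w = canvas.shape[:2]
    pad = int(np.ceil(r + 3 * softness)) + 1
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - x, yy - y)
    alpha = np.clip((r + softness - d) / (2.0 * softness), 0.0, 1.0) * alpha_max
    patch = canvas[y0:y1, x0:x1]
    patch *= (1.0 - alpha)[..., None]
    patch += alpha[..., None] * rgb


def _paint_blob(canvas: np.ndarray, x: float, y: float, r: float, rgb: np.ndarray,
                alpha_max: float = 0.45) -> None:
    """Gaussian-profile diffuse blob (cell stain): low gradients on purpose."""
    h, w = canvas.shape[:2]
    pad = int(np.ceil(2.5 * r))
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    alpha = alpha_max * np.exp(-d2 / (2.0 * (r * 0.75) ** 2))
    patch = canvas[y0:y1, x0:x1]
    patch *= (1.0 - alpha)[..., None]
    patch += alpha[..., None] * rgb


def paint_signal(canvas: np.ndarray, x: float, y: float, r: float,
                 label: SignalLabel, rng: np.random.Generator) -> None:
    """Paint one signal with the class's canonical appearance."""
    if label is SignalLabel.GENE:
        _paint_disk(canvas, x, y, r, _GENE_RGB)
    elif label is SignalLabel.CEP:
        _paint_disk(canvas, x, y, r, _CEP_RGB)
    elif label is SignalLabel.GENE_CEP_MIXED:
        # overlapping black + red chromogens, offset well under the NMS radius
        a = rng.uniform(0, 2 * np.pi)
        dx, dy = 1.5 * np.cos(a), 1.5 * np.sin(a)
        _paint_disk(canvas, x - dx / 2, y - dy / 2, r, _GENE_RGB)
        _paint_disk(canvas, x + dx / 2, y + dy / 2, r * 0.9, _CEP_RGB, alpha_max=0.85)
    elif label is SignalLabel.NOISE:
        _paint_disk(canvas, x, y, r, _NOISE_RGB, softness=1.0, alpha_max=0.9)
    elif label is SignalLabel.CELL_STAIN:
        _paint_blob(canvas, x, y, r, _STAIN_RGB)


def _paint_background(canvas: np.ndarray, mask: DiskMask, rng: np.random.Generator) -> None:
    """Pale textured hematoxylin inside the tissue disk, white outside."""
    from scipy import ndimage as ndi

    x0, y0, x1, y1 = mask.bounds
    hh, ww = y1 - y0, x1 - x0
    if hh <= 0 or ww <= 0:
        return
    texture = rng.standard_normal((hh, ww)).astype(np.float32)
    texture = ndi.gaussian_filter(texture, 6.0)
    texture *= 0.02 / max(texture.std(), 1e-9)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = np.asarray(mask.contains(xx, yy))
    region = canvas[y0:y1, x0:x1]
    base = _BACKGROUND_RGB[None, None, :] + texture[..., None]
    region[inside] = base[inside]


def render_core(truth: GroundTruth, spec: SyntheticCoreSpec | None = None,
                canvas: np.ndarray | None = None) -> RasterImage:
    """Render a ground-truth point set into a bright-field-like RGB image.

    The whole render is driven by ``spec.seed``, so identical specs give
    pixel-identical images.  If ``canvas`` is given (float32 HxWx3 in
    [0,1]), painting happens in place and the blur/noise stage is skipped —
    used by :func:`generate_slide` to compose mosaics before a single final
    blur+noise pass.
    """
    from scipy import ndimage as ndi

    spec = spec or truth.spec
    own_canvas = canvas is None
    if own_canvas:
        canvas = np.empty((spec.canvas_size, spec.canvas_size, 3), dtype=np.float32)
        canvas.fill(1.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 202]))
    _paint_background(canvas, truth.mask, rng)
    # stains go under the dots, like out-of-plane cytoplasm
    order = {SignalLabel.CELL_STAIN: 0, SignalLabel.NOISE: 1}
    for p in sorted(truth.points, key=lambda q: (order.get(q.label, 2), q.x, q.y)):
        paint_signal(canvas, p.x, p.y, p.radius, p.label, rng)
    if not own_canvas:
        return RasterImage(np.clip(canvas * 255.0, 0, 255).astype(np.uint8))
    # separate stream so a 1-core mosaic reproduces this output exactly
    return finish_render(canvas, np.random.default_rng(np.random.SeedSequence([int(spec.seed), 303])))


def finish_render(canvas: np.ndarray, rng: np.random.Generator) -> RasterImage:
    """Optics + sensor model: slight blur, then additive Gaussian noise."""
    from .raster import blur_inplace_chunked

    for c in range(3):
        blur_inplace_chunked(canvas[..., c], 0.8)
    # add noise in fixed 512-row blocks: bounds peak memory on slide-sized
    # canvases while staying deterministic for a given generator state
    h = canvas.shape[0]
    for y0 in range(0, h, 512):
        block = canvas[y0:y0 + 512]
        noise = rng.standard_normal(size=block.shape, dtype=np.float32)
        noise *= 0.008
        block += noise
    np.clip(canvas, 0.0, 1.0, out=canvas)
    canvas *= 255.0
    np.rint(canvas, out=canvas)
    return RasterImage(canvas.astype(np.uint8))


@dataclass
class SlideGroundTruth:
    """Stitched truth for a rendered mosaic slide."""

    cores: list[GroundTruth]  # truths already shifted to global coordinates
    grid_shape: tuple[int, int]
    tile_size: int

    @property
    def points(self) -> list[SignalPoint]:
        return [p for t in self.cores for p in t.points]

    @property
    def frame(self) -> pd.DataFrame:
        frames = []
        for i, t in enumerate(self.cores):
            f = t.frame.copy()
            f["core_id"] = i
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def generate_slide(specs) -> tuple[RasterImage, SlideGroundTruth]:
    """Render a mosaic of cores: ``specs`` is a 2-D nested list (rows of
    :class:`SyntheticCoreSpec`); each grid cell is one core tile.  A scaled
    -down stand-in for a whole slide: the tiling/merging logic downstream is
    identical, only the canvas is desk-sized (4 x 4 cores = 16384^2)."""
    rows = [list(r) for r in specs]
    if not rows or not rows[0]:
        raise ParameterError("generate_slide needs at least one core spec")
    ncols = max(len(r) for r in rows)
    tile = rows[0][0].canvas_size
    H, W = tile * len(rows), tile * ncols
    canvas = np.empty((H, W, 3), dtype=np.float32)
    canvas.fill(1.0)
    shifted = []
    first_seed = rows[0][0].seed
    for iy, row in enumerate(rows):
        for ix, spec in enumerate(row):
            if spec is None:
                continue
            truth = generate_point_set(spec)
            sub = canvas[iy * tile:(iy + 1) * tile, ix * tile:(ix + 1) * tile]
            render_core(truth, spec, canvas=sub)
            shifted.append(truth.shifted(ix * tile, iy * tile))
    rng = np.random.default_rng(np.random.SeedSequence([int(first_seed), 303]))
    image = finish_render(canvas, rng)
    return image, SlideGroundTruth(cores=shifted, grid_shape=(len(rows), ncols), tile_size=tile)


# ---------------------------------------------------------------------------
# training data

def generate_training_set(crops_per_class: int = 500, seed: int = 0,
                          canvas_size: int = 1536):
    """Balanced annotated signals for classifier training.

    One single-class canvas per label: signals are planted on a grid with
    jitter over the same hematoxylin background and painted by the same
    renderer as full cores, so crops carry the classes' canonical palette.
    Returns a list of :class:`~ishquant.classification.AnnotatedSignal`.
    """
    from .classification import AnnotatedSignal

    if crops_per_class < 10:
        raise GenerationError("crops_per_class must be >= 10")
    out = []
    for ci, label in enumerate(SignalLabel):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404, ci]))
        if label is SignalLabel.CELL_STAIN:
            spacing = 110.0
        else:
            spacing = 48.0
        per_row = int(canvas_size // spacing) - 1
        capacity = per_row * per_row
        size = canvas_size
        while capacity < crops_per_class:
            size += canvas_size
            per_row = int(size // spacing) - 1
            capacity = per_row * per_row
        canvas = np.ones((size, size, 3), dtype=np.float32)
        mask = DiskMask(size / 2, size / 2, size, (size, size))  # covers canvas
        _paint_background(canvas, mask, rng)
        pts = []
        for iy in range(per_row):
            for ix in range(per_row):
                if len(pts) >= crops_per_class:
                    break
                x = spacing * (ix + 1) + rng.uniform(-6, 6)
                y = spacing * (iy + 1) + rng.uniform(-6, 6)
                if label is SignalLabel.CELL_STAIN:
                    r = rng.uniform(18.0, 30.0)
                elif label is SignalLabel.NOISE:
                    r = rng.uniform(3.0, 4.5)
                else:
                    r = rng.uniform(3.5, 5.5)
                paint_signal(canvas, x, y, r, label, rng)
                # the classifier sees the detector's radius estimate, which is
                # clipped to the Hough range; reflect that for stains
                ann_r = min(r, 10.0) if label is SignalLabel.CELL_STAIN else r
                pts.append(SignalPoint(x=x, y=y, radius=ann_r, label=label))
        image = finish_render(canvas, rng)
        out.extend(AnnotatedSignal(image=image, point=p, label=label) for p in pts)
    return out
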