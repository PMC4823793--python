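"""Multi-level tumour-heterogeneity statistics.

The global ratio collapses a core to one number; heterogeneity lives in the
*distribution* of local ratios.  Two randomized statistics capture it:

RLR (randomized local ratio)
    Draw random points uniformly over the tissue region (default 300), snap
    each to its nearest not-yet-used CEP signal, and in a fixed-radius disk
    (default 60 px — wide enough to take in at least one adjacent cell)
    around each anchor compute gene count / CEP count.

RLD (randomized local density)
    Same neighbourhoods; the statistic is the total gene + CEP count.

Per core, mean / median / SEM of each distribution give a 6-D feature
vector.  Cohorts of cores are z-scored, embedded by PCA into 2-D, clustered
with full-covariance Gaussian mixtures whose component count k = 1..5 is
picked by minimum AIC, and graded by Mahalanobis distance to the centroid
of the homogeneous-deletion component (the cluster whose members have the
lowest mean RLR).  Robustness of each core's position is summarized by a
95% confidence ellipse over repeated runs that vary the number of random
points from 201 to 300.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .errors import AnalysisError, HeterogeneityError, ParameterError
from .points import SignalLabel, SignalPoint
from .scoring import MixedPolicy

DEFAULT_N_RANDOM = 300
DEFAULT_RADIUS = 60.0
FEATURE_ORDER = ("rlr_mean", "rlr_median", "rlr_sem", "rld_mean", "rld_median", "rld_sem")


@dataclass(frozen=True)
class HeterogeneityParams:
    n_random: int = DEFAULT_N_RANDOM
    radius: float = DEFAULT_RADIUS
    seed: int = 0
    mixed_policy: MixedPolicy = MixedPolicy.COUNT_BOTH

    def __post_init__(self):
        if self.n_random < 1:
            raise ParameterError("n_random must be >= 1")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")


@dataclass
class LocalDistributions:
    """RLR and RLD samples for one core (paired per anchor)."""

    rlr: np.ndarray  # float ratios
    rld: np.ndarray  # int densities
    params: HeterogeneityParams

    def __post_init__(self):
        if len(self.rlr) != len(self.rld):
            raise AnalysisError("RLR and RLD must be paired per anchor")


@dataclass(frozen=True)
class CoreFeatureVector:
    rlr_mean: float
    rlr_median: float
    rlr_sem: float
    rld_mean: float
    rld_median: float
    rld_sem: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_ORDER], dtype=float)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n_cores, 2)
    loadings: np.ndarray  # (n_kept_features, 2)
    explained_variance: np.ndarray  # (2,)
    feature_means: np.ndarray
    feature_sds: np.ndarray
    kept_features: tuple[str, ...]

    def project(self, features: np.ndarray) -> np.ndarray:
        """Project raw 6-D feature rows with the frozen standardization."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        keep = [FEATURE_ORDER.index(k) for k in self.kept_features]
        Z = (X[:, keep] - self.feature_means) / self.feature_sds
        return Z @ self.loadings


@dataclass
class MixtureModel:
    k: int
    weights: np.ndarray
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    aic: float
    assignments: np.ndarray  # hard labels per core
    seed: int
    aic_by_k: dict[int, float] = field(default_factory=dict)


@dataclass
class PerturbationEllipse:
    center: np.ndarray  # (2,)
    axes: tuple[float, float]  # half-lengths, major first
    orientation: float  # radians of major axis
    n_reps: int

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])


# ---------------------------------------------------------------------------
# anchors and local statistics

def _cep_coords(points: Sequence[SignalPoint], policy: MixedPolicy) -> np.ndarray:
    labels = {SignalLabel.CEP}
    if policy is MixedPolicy.COUNT_BOTH:
        labels.add(SignalLabel.GENE_CEP_MIXED)
    return np.array([(p.x, p.y) for p in points if p.label in labels], dtype=float).reshape(-1, 2)


def snap_without_replacement(draws: np.ndarray, cep: np.ndarray) -> np.ndarray:
    """Snap each draw, in order, to its nearest not-yet-used CEP point.

    Returns the CEP index chosen for each draw.  Once a CEP anchors a
    neighbourhood it is removed from further snapping ("without
    replacement").  Needs ``len(draws) <= len(cep)``.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1, 2)
    if len(draws) > len(cep):
        raise HeterogeneityError("more draws than available CEP points")
    tree = cKDTree(cep)
    used = np.zeros(len(cep), dtype=bool)
    out = np.empty(len(draws), dtype=int)
    for i, (x, y) in enumerate(draws):
        k = 8
        snapped = None
        while snapped is None:
            k = min(k, len(cep))
            _, idx = tree.query((x, y), k=k)
            for j in np.atleast_1d(idx):
                if not used[j]:
                    snapped = int(j)
                    break
            if snapped is None:
                k *= 4  # all k nearest already used; widen (k==len(cep) cannot fail)
        used[snapped] = True
        out[i] = snapped
    return out


def uniform_tissue_draws(mask, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points inside the tissue region, by rejection from its
    bounding box.  ``mask`` is anything with ``contains(x, y)`` and
    ``bounds`` (a raster :class:`~ishquant.raster.TissueMask` or an
    analytic :class:`~ishquant.synthetic.DiskMask`)."""
    x0, y0, x1, y1 = mask.bounds
    out = []
    for _guard in range(500):
        batch = max(4 * (n - len(out)), 64)
        xs = rng.uniform(x0, x1, size=batch)
        ys = rng.uniform(y0, y1, size=batch)
        inside = np.asarray(mask.contains(xs, ys))
        out.extend(zip(xs[inside], ys[inside]))
        if len(out) >= n:
            return np.asarray(out[:n], dtype=float)
    raise HeterogeneityError("could not draw uniform points inside the tissue mask")


def sample_anchor_points(
    points: Sequence[SignalPoint],
    mask,
    params: HeterogeneityParams,
    draws: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform spatial draws over the tissue, snapped to distinct CEP signals.

    Sampling is without replacement: a CEP that already anchors a
    neighbourhood is removed from further snapping, so no CEP is used
    twice.  If there are at most ``n_random`` CEPs, all of them become
    anchors.  ``draws`` overrides the uniform draws (testing hook).
    Returns (n, 2) anchor coordinates.
    """
    cep = _cep_coords(points, params.mixed_policy)
    if len(cep) == 0:
        raise HeterogeneityError("no CEP-labeled points: cannot anchor neighbourhoods")
    if len(cep) <= params.n_random:
        return cep.copy()
    if draws is None:
        rng = np.random.default_rng(params.seed)
        draws = uniform_tissue_draws(mask, params.n_random, rng)
    idx = snap_without_replacement(np.asarray(draws)[: params.n_random], cep)
    return cep[idx]


def compute_rlr_rld(
    points: Sequence[SignalPoint],
    anchors: np.ndarray,
    params: HeterogeneityParams,
) -> LocalDistributions:
    """Exact disk-membership counts around each anchor.

    Gene count / CEP count and gene + CEP count over all scored points
    within Euclidean distance <= radius of the anchor; a mixed signal adds
    one to each channel under ``count_both`` and is dropped under
    ``exclude``.  The anchor itself is a CEP, so every local CEP count is
    >= 1 and the ratio is always defined.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 2)
    gene = np.array(
        [(p.x, p.y) for p in points if p.label is SignalLabel.GENE], dtype=float
    ).reshape(-1, 2)
    cep = np.array(
        [(p.x, p.y) for p in points if p.label is SignalLabel.CEP], dtype=float
    ).reshape(-1, 2)
    mixed = np.array(
        [(p.x, p.y) for p in points if p.label is SignalLabel.GENE_CEP_MIXED], dtype=float
    ).reshape(-1, 2)

    def count_within(pts: np.ndarray) -> np.ndarray:
        if len(pts) == 0 or len(anchors) == 0:
            return np.zeros(len(anchors), dtype=int)
        tree = cKDTree(pts)
        return np.array(
            [len(ix) for ix in tree.query_ball_point(anchors, params.radius)], dtype=int
        )

    g = count_within(gene)
    c = count_within(cep)
    if params.mixed_policy is MixedPolicy.COUNT_BOTH and len(mixed):
        m = count_within(mixed)
        g = g + m
        c = c + m
    if np.any(c < 1):
        raise HeterogeneityError(
            "anchor neighbourhood without a CEP signal: anchors must be CEP points"
        )
    rlr = g / c
    rld = g + c
    return LocalDistributions(rlr=rlr.astype(float), rld=rld.astype(int), params=params)


def summarize_features(dists: LocalDistributions) -> CoreFeatureVector:
    """Mean / median / SEM of RLR and RLD (sample SD, n-1 denominator)."""
    rlr, rld = dists.rlr, dists.rld
    if len(rlr) < 2:
        raise AnalysisError("need >= 2 local samples to summarize a core")
    n = len(rlr)
    return CoreFeatureVector(
        rlr_mean=float(np.mean(rlr)),
        rlr_median=float(np.median(rlr)),
        rlr_sem=float(np.std(rlr, ddof=1) / np.sqrt(n)),
        rld_mean=float(np.mean(rld)),
        rld_median=float(np.median(rld)),
        rld_sem=float(np.std(rld, ddof=1) / np.sqrt(n)),
    )


def core_features(
    points: Sequence[SignalPoint], mask, params: HeterogeneityParams
) -> CoreFeatureVector:
    """Convenience: anchors -> RLR/RLD -> 6-D summary for one core."""
    anchors = sample_anchor_points(points, mask, params)
    return summarize_features(compute_rlr_rld(points, anchors, params))


# ---------------------------------------------------------------------------
# embedding / clustering

def embed_pca(features: Sequence[CoreFeatureVector] | np.ndarray) -> EmbeddingResult:
    """Z-score the 6 features, project onto the top-2 principal components.

    Constant feature columns are dropped with a warning (they carry no
    variance to embed).  Component signs are fixed so the largest-magnitude
    loading of each component is positive, making embeddings reproducible.
    """
    import warnings

    if not isinstance(features, np.ndarray):
        X = np.vstack([f.as_array() for f in features])
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise AnalysisError("PCA embedding needs >= 3 cores")
    sds = X.std(axis=0)
    keep = sds > 1e-12
    if not keep.all():
        dropped = [FEATURE_ORDER[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping constant feature column(s): {dropped}", stacklevel=2)
    Xk = X[:, keep]
    mu = Xk.mean(axis=0)
    sd = Xk.std(axis=0)
    Z = (Xk - mu) / sd
    cov = np.atleast_2d(np.cov(Z, rowvar=False))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:2]
    load = evecs[:, order]
    evar = evals[order]
    if load.shape[1] < 2:  # a single informative feature: pad PC2 with zeros
        load = np.hstack([load, np.zeros((load.shape[0], 2 - load.shape[1]))])
        evar = np.concatenate([evar, np.zeros(2 - len(evar))])
    for j in range(load.shape[1]):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    return EmbeddingResult(
        coords=Z @ load,
        loadings=load,
        explained_variance=np.asarray(evar, dtype=float),
        feature_means=mu,
        feature_sds=sd,
        kept_features=tuple(np.array(FEATURE_ORDER)[keep]),
    )


def select_k_by_aic(
    coords: np.ndarray, k_max: int = 5, seed: int = 0, reg_fraction: float = 0.05
) -> MixtureModel:
    """Fit full-covariance GMMs for k = 1..k_max, keep the minimum-AIC one.

    EM with k-means initialization and 10 restarts per k, seeded.  AIC =
    2p - 2 log L with p = (k-1) + 2k + 3k free parameters in 2-D.  Ties
    resolve to the smaller k.

    ``reg_fraction`` sets a per-dimension covariance floor of that fraction
    of the data's mean variance.  Without it, restarted EM reliably finds
    degenerate "sliver" components (a handful of near-collinear points with
    near-singular covariance) whose inflated likelihood tricks AIC into
    overselecting k; a floor at a few percent of the data spread removes
    those while leaving honestly separated clusters untouched.
    """
    from sklearn.mixture import GaussianMixture

    coords = np.asarray(coords, dtype=float)
    if len(coords) <= k_max:
        raise AnalysisError(f"need more than k_max={k_max} points, got {len(coords)}")
    reg = max(float(reg_fraction) * float(coords.var(axis=0).mean()), 1e-9)
    best = None
    aic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            init_params="kmeans",
            random_state=seed,
            reg_covar=reg,
            max_iter=500,
        ).fit(coords)
        if not gm.converged_:
            raise AnalysisError(f"EM failed to converge for k={k} after restarts")
        aic = float(gm.aic(coords))
        aic_by_k[k] = aic
        if best is None or aic < best[0]:
            best = (aic, k, gm)
    aic, k, gm = best
    return MixtureModel(
        k=k,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        aic=aic,
        assignments=gm.predict(coords),
        seed=seed,
        aic_by_k=aic_by_k,
    )


def mahalanobis_distances(coords: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """d(x) = sqrt((x - mu)^T Sigma^-1 (x - mu)) per point."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise AnalysisError(f"covariance is not positive-definite: {exc}") from exc
    diff = coords - mean
    sol = linalg.solve_triangular(chol, diff.T, lower=True)
    return np.sqrt((sol**2).sum(axis=0))


def identify_reference_component(
    model: MixtureModel, features: Sequence[CoreFeatureVector]
) -> int:
    """Component whose member cores have the lowest mean RLR — the
    homogeneous-deletion cluster (deletion means a low gene:CEP ratio).
    Empty components are excluded; ties go to the lower index."""
    rlr = np.array([f.rlr_mean for f in features])
    best_idx = None
    best_val = np.inf
    for comp in range(model.k):
        members = model.assignments == comp
        if not members.any():
            continue
        val = float(rlr[members].mean())
        if val < best_val:
            best_val = val
            best_idx = comp
    if best_idx is None:
        raise AnalysisError("all mixture components are empty")
    return best_idx


# ---------------------------------------------------------------------------
# perturbation ellipses

def confidence_ellipse(cloud: np.ndarray, level: float = 0.95, n_reps: int | None = None) -> PerturbationEllipse:
    """95% confidence ellipse of a 2-D point cloud: covariance eigenaxes
    scaled by the chi-square(2) quantile."""
    cloud = np.asarray(cloud, dtype=float)
    center = cloud.mean(axis=0)
    if len(cloud) < 2:
        raise AnalysisError("need >= 2 repetitions for an ellipse")
    cov = np.cov(cloud, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = chi2.ppf(level, df=2)
    half = np.sqrt(evals * scale)
    major = int(np.argmax(half))
    minor = 1 - major
    orientation = float(np.arctan2(evecs[1, major], evecs[0, major]))
    return PerturbationEllipse(
        center=center,
        axes=(float(half[major]), float(half[minor])),
        orientation=orientation,
        n_reps=n_reps if n_reps is not None else len(cloud),
    )


def perturbation_ellipses(
    cores: Sequence[tuple[Sequence[SignalPoint], object]],
    embedding: EmbeddingResult,
    n_range: tuple[int, int] = (201, 300),
    reps: int = 100,
    base_seed: int = 0,
    radius: float = DEFAULT_RADIUS,
    mixed_policy: MixedPolicy = MixedPolicy.COUNT_BOTH,
) -> list[PerturbationEllipse]:
    """Robustness ellipses: rerun sample -> RLR/RLD -> summary ``reps``
    times per core, cycling n_random over ``n_range`` (repetition i uses
    n_random = n_range[0] + (i-1) mod span and seed = base_seed + i), and
    project every repetition with the cohort's frozen PCA.  Each core's
    ellipse is the 95% confidence ellipse of its repetition cloud.
    """
    if reps < 2:
        raise ParameterError("reps must be >= 2")
    lo, hi = n_range
    span = hi - lo + 1
    out = []
    for points, mask in cores:
        cloud = np.zeros((reps, 2))
        for i in range(1, reps + 1):
            params = HeterogeneityParams(
                n_random=lo + (i - 1) % span,
                radius=radius,
                seed=base_seed + i,
                mixed_policy=mixed_policy,
            )
            feat = core_features(points, mask, params)
            cloud[i - 1] = embedding.project(feat.as_array())[0]
        out.append(confidence_ellipse(cloud, n_reps=reps))
    return out
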