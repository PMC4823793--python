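"""Per-signal appearance features and the five-class SVM.

Detected dots are told apart almost entirely by hue and darkness: silver
gene dots are near-black, CEP dots red, colocalized mixed dots dark with a
strong red chroma, debris is faint and brownish, cell stains are large,
pale and bluish.  A 14-dimensional colour/intensity/contrast feature vector
is extracted from the disk around each detection and fed to an RBF-kernel
support-vector machine (one-vs-one multiclass, inverse-frequency class
weights), with hyperparameters picked by grid search inside a stratified
5-fold cross-validation.
"""
from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ModelError, TrainingError
from .points import SignalLabel, SignalPoint
from .raster import RasterImage, load_image

FEATURE_NAMES = (
    "r_mean", "g_mean", "b_mean",
    "r_sd", "g_sd", "b_sd",
    "a_chroma_mean", "b_chroma_mean",
    "radius",
    "ring_disk_contrast",
    "disk_luminance",
    "disk_luminance_sd",
    "gradient_magnitude",
    "saturation_mean",
)

CLASS_ORDER = tuple(l.value for l in SignalLabel)

#: default grid-search ranges
C_GRID = (0.1, 1.0, 10.0, 100.0)
GAMMA_FACTORS = tuple(2.0**k for k in range(-4, 3))


@dataclass(frozen=True)
class AnnotatedSignal:
    """One expert-annotated (here: planted) training example.

    ``image`` may be an in-memory :class:`RasterImage` or a file path.
    """

    image: RasterImage | str | Path
    point: SignalPoint
    label: SignalLabel


def _resolve_image(image, cache: dict | None = None) -> RasterImage:
    if isinstance(image, RasterImage):
        return image
    key = str(image)
    if cache is not None and key in cache:
        return cache[key]
    img = load_image(image)
    if cache is not None:
        cache[key] = img
    return img


# ---------------------------------------------------------------------------
# features

def _srgb_to_lab_ab(rgb_mean: np.ndarray) -> tuple[float, float]:
    """a*, b* of a mean sRGB colour (enough chroma signal for dot hues)."""
    from skimage.color import rgb2lab

    lab = rgb2lab(rgb_mean.reshape(1, 1, 3).astype(np.float64))
    return float(lab[0, 0, 1]), float(lab[0, 0, 2])


def extract_features(image: RasterImage, point: SignalPoint,
                     _float_image: np.ndarray | None = None) -> np.ndarray:
    """14-dim appearance vector for one signal (see :data:`FEATURE_NAMES`).

    Disk = pixels within the point's radius; ring = an annulus from radius
    to 2x radius.  Both are clipped at image borders.  Deterministic per
    (image, point).
    """
    h, w = image.shape
    r = max(float(point.radius), 1.5)
    ring_r = 2.0 * r
    pad = int(np.ceil(ring_r)) + 1
    x0, x1 = max(0, int(point.x) - pad), min(w, int(point.x) + pad + 1)
    y0, y1 = max(0, int(point.y) - pad), min(h, int(point.y) + pad + 1)
    if _float_image is not None:
        patch = _float_image[y0:y1, x0:x1]
    else:  # convert just the crop: keeps whole-slide extraction cheap
        patch = image.pixels[y0:y1, x0:x1].astype(np.float32) / 255.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - point.x, yy - point.y)
    disk = d <= r
    ring = (d > r) & (d <= ring_r)
    if not disk.any():
        disk = d <= d.min() + 0.5
    if not ring.any():
        ring = disk

    disk_px = patch[disk]  # (n, 3)
    ring_px = patch[ring]
    rgb_mean = disk_px.mean(axis=0)
    rgb_sd = disk_px.std(axis=0)
    a_star, b_star = _srgb_to_lab_ab(rgb_mean)
    lum_w = np.array([0.299, 0.587, 0.114])
    disk_lum = disk_px @ lum_w
    ring_lum = ring_px @ lum_w
    contrast = float(ring_lum.mean() - disk_lum.mean())
    mx = disk_px.max(axis=1)
    mn = disk_px.min(axis=1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    # mean absolute luminance step over the patch: cheap local gradient proxy
    lum_patch = patch @ lum_w
    if lum_patch.size > 4:
        grad = float(
            np.abs(np.diff(lum_patch, axis=0)).mean()
            + np.abs(np.diff(lum_patch, axis=1)).mean()
        )
    else:
        grad = 0.0
    return np.array(
        [
            rgb_mean[0], rgb_mean[1], rgb_mean[2],
            rgb_sd[0], rgb_sd[1], rgb_sd[2],
            a_star, b_star,
            float(point.radius),
            contrast,
            float(disk_lum.mean()),
            float(disk_lum.std()),
            grad,
            float(sat.mean()),
        ],
        dtype=float,
    )


def extract_features_batch(image: RasterImage, points) -> np.ndarray:
    """(n, 14) feature matrix.

    Small images are converted to float once and shared across points;
    slide-sized rasters are handled crop by crop to avoid a full-frame
    float copy.
    """
    if not points:
        return np.zeros((0, len(FEATURE_NAMES)))
    f = image.as_float() if image.pixels.nbytes <= 2**28 else None
    return np.vstack([extract_features(image, p, _float_image=f) for p in points])


# ---------------------------------------------------------------------------
# classifier

@dataclass
class SignalClassifier:
    """Trained 5-class SVM plus the metadata needed to trust it later."""

    model: object  # sklearn Pipeline(StandardScaler -> SVC)
    feature_spec: tuple[str, ...]
    cv_report: dict  # {"fold_accuracy": [...5 floats], "mean_accuracy": float, "best_params": {...}}
    classes: tuple[str, ...] = CLASS_ORDER
    seed: int = 0
    version: str = "1"

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SignalClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, SignalClassifier):
            raise ModelError(f"{path} does not contain a SignalClassifier")
        return obj


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """1 / median squared pairwise distance on (standardized) subsample."""
    n = min(len(X), 400)
    idx = rng.choice(len(X), size=n, replace=False)
    sub = X[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    med = np.median(d2[np.triu_indices(n, k=1)])
    return 1.0 / max(med, 1e-9)


def train_classifier(training: list[AnnotatedSignal], seed: int = 0) -> SignalClassifier:
    """Fit the RBF SVM with grid-searched (C, gamma) under stratified 5-fold CV.

    Requires all five classes with >= 10 examples each.  Ties in the grid
    resolve to the smaller C (grid order).  The final model is refit on all
    data.
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    counts = {l: 0 for l in SignalLabel}
    for a in training:
        counts[a.label] += 1
    missing = [l.value for l, c in counts.items() if c < 10]
    if missing:
        raise TrainingError(
            f"need >= 10 examples of every class; short or absent: {missing}"
        )

    cache: dict = {}
    by_image: dict[int, tuple[RasterImage, list[int]]] = {}
    X = np.zeros((len(training), len(FEATURE_NAMES)))
    # group by image so each raster is converted to float once
    for i, a in enumerate(training):
        img = _resolve_image(a.image, cache)
        by_image.setdefault(id(img), (img, []))[1].append(i)
    for img, idxs in by_image.values():
        f = img.as_float()
        for i in idxs:
            X[i] = extract_features(img, training[i].point, _float_image=f)
    y = np.array([a.label.value for a in training])

    rng = np.random.default_rng(seed)
    scaler = StandardScaler().fit(X)
    gamma0 = _median_heuristic_gamma(scaler.transform(X), rng)
    grid = {
        "svc__C": list(C_GRID),
        "svc__gamma": [gamma0 * f for f in GAMMA_FACTORS],
    }
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", class_weight="balanced", random_state=seed)),
        ]
    )
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", refit=False, n_jobs=1)
    search.fit(X, y)
    best = int(search.best_index_)
    folds = [float(search.cv_results_[f"split{k}_test_score"][best]) for k in range(5)]
    best_params = {k.split("__")[1]: float(v) for k, v in search.best_params_.items()}

    final = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel="rbf",
                    C=best_params["C"],
                    gamma=best_params["gamma"],
                    class_weight="balanced",
                    random_state=seed,
                ),
            ),
        ]
    ).fit(X, y)

    return SignalClassifier(
        model=final,
        feature_spec=FEATURE_NAMES,
        cv_report={
            "fold_accuracy": folds,
            "mean_accuracy": float(np.mean(folds)),
            "best_params": best_params,
        },
        seed=seed,
    )


def classify_signals(
    classifier: SignalClassifier, image: RasterImage, points: list[SignalPoint]
) -> list[SignalPoint]:
    """Label every point; ``label_score`` is a softmax-normalized
    decision-margin confidence in [0, 1] for the winning class."""
    if tuple(classifier.feature_spec) != FEATURE_NAMES:
        raise ModelError(
            "model feature_spec does not match this package's extractor: "
            f"{classifier.feature_spec} vs {FEATURE_NAMES}"
        )
    if not points:
        return []
    X = extract_features_batch(image, points)
    n_expected = getattr(classifier.model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ModelError(
            f"feature length mismatch: extractor gives {X.shape[1]}, model expects {n_expected}"
        )
    pred = classifier.model.predict(X)
    margins = np.atleast_2d(classifier.model.decision_function(X))
    margins -= margins.max(axis=1, keepdims=True)
    soft = np.exp(margins)
    soft /= soft.sum(axis=1, keepdims=True)
    model_classes = list(classifier.model.classes_)
    out = []
    for p, cls, row in zip(points, pred, soft):
        out.append(p.with_label(SignalLabel(cls), float(row[model_classes.index(cls)])))
    return out
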