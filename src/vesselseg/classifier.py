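"""Pixelwise RBF-SVM vessel classification.

Training pixels are drawn uniformly at random (without replacement) from
each training image's FOV — about 12% of fundus FOV pixels are vessel, and
the sampling preserves that imbalance.  A support vector machine with RBF
kernel (C = 1, bandwidth gamma = 0.01 by default; optionally selected by
5-fold cross-validated grid search) is trained on the normalized
23-component descriptors.  Scoring a test image produces a signed
decision-value image: positive values lie on the vessel side of the
separating surface, zero is the class boundary, and the dual-threshold
postprocessing cuts are taken on this scale.

:class:`VesselSegmenter` packages the whole pipeline as a scikit-learn
style estimator: ``fit`` on (image, ground-truth) pairs,
``decision_function`` for the score image of a new fundus image, and
``predict`` for the final postprocessed binary map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .descriptor import COMPONENT_NAMES, build_descriptors, normalize_descriptors
from .image import IntensityImage
from .lineset import LineSetConfig
from .local_features import IntensityFeatureConfig

#: cross-validated search grid when hyperparameter search is enabled;
#: iteration order (C ascending, then gamma ascending) breaks score ties
#: toward smaller C then smaller gamma.
DEFAULT_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.001, 0.01, 0.1, 1.0]}


@dataclass(frozen=True)
class TrainingConfig:
    samples_per_image: int = 20000
    rng_seed: int = 0
    svm_c: float = 1.0
    rbf_bandwidth: float = 0.01
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.samples_per_image < 1:
            raise ValueError("samples_per_image must be >= 1")
        if self.svm_c <= 0 or self.rbf_bandwidth <= 0:
            raise ValueError("svm_c and rbf_bandwidth must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ScoreImage:
    """Per-pixel SVM decision values; NaN outside the FOV."""

    scores: np.ndarray
    fov: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.fov = np.asarray(self.fov, dtype=bool)
        if self.scores.shape != self.fov.shape:
            raise ValueError("scores and fov shapes differ")
        if not np.isfinite(self.scores[self.fov]).all():
            raise ValueError("non-finite score inside FOV")


def sample_training_pixels(
    image: IntensityImage,
    ground_truth: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n distinct FOV pixels uniformly at random.

    Returns ``(coords, labels)``: coords of shape (n, 2) in (row, col) and
    boolean vessel labels from the ground truth.  Deterministic given the
    seed; the draw is without replacement over the FOV in row-major order.
    """
    ground_truth = np.asarray(ground_truth, dtype=bool)
    if ground_truth.shape != image.shape:
        raise ValueError("ground truth shape does not match image")
    rows, cols = np.nonzero(image.fov)
    if n > rows.size:
        raise ValueError(f"requested {n} samples but FOV has {rows.size} pixels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    coords = np.stack([rows[idx], cols[idx]], axis=1)
    labels = ground_truth[coords[:, 0], coords[:, 1]]
    return coords, labels


def train(
    training_table: pd.DataFrame,
    config: TrainingConfig | None = None,
    grid_search: bool = False,
    probability: bool = False,
) -> SVC:
    """Train the RBF-SVM on a table of descriptors plus a ``label`` column.

    With ``grid_search`` the (C, gamma) pair maximizing mean 5-fold CV
    accuracy over :data:`DEFAULT_GRID` is selected (ties broken toward
    smaller C, then smaller gamma); otherwise the configured defaults
    (C = 1, gamma = 0.01) are used directly.
    """
    config = config or TrainingConfig()
    X = training_table[COMPONENT_NAMES].to_numpy(dtype=np.float64)
    y = training_table["label"].to_numpy(dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    extra = {"probability": True} if probability else {}
    if grid_search:
        search = GridSearchCV(
            SVC(kernel="rbf", **extra),
            DEFAULT_GRID,
            cv=config.cv_folds,
            scoring="accuracy",
        )
        search.fit(X, y)
        model = search.best_estimator_
    else:
        model = SVC(
            kernel="rbf",
            C=config.svm_c,
            gamma=config.rbf_bandwidth,
            cache_size=500,
            **extra,
        )
        model.fit(X, y)
    return model


def score_image(
    model: SVC, descriptor_table: pd.DataFrame, image_shape: tuple[int, int]
) -> ScoreImage:
    """Evaluate the SVM decision function at every FOV pixel of one image."""
    X = descriptor_table[COMPONENT_NAMES].to_numpy(dtype=np.float64)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"descriptor dimension {X.shape[1]} != model dimension {model.n_features_in_}"
        )
    values = model.decision_function(X)
    scores = np.full(image_shape, np.nan)
    fov = np.zeros(image_shape, dtype=bool)
    rows = descriptor_table["row"].to_numpy()
    cols = descriptor_table["col"].to_numpy()
    scores[rows, cols] = values
    fov[rows, cols] = True
    return ScoreImage(scores, fov)


class VesselSegmenter(BaseEstimator):
    """Fundus vessel segmentation: line-set descriptors -> RBF-SVM -> dual
    thresholds with morphological reconstruction.

    Parameters
    ----------
    s : float
        Line-search homogeneity threshold S, in grey levels.
    samples_per_image : int
        Training pixels drawn uniformly from each training image's FOV.
    C, gamma : float
        RBF-SVM regularization and kernel bandwidth.
    grid_search : bool
        Select (C, gamma) by 5-fold cross-validation over the documented
        grid instead of using the fixed values.
    base_threshold, marker_threshold : float
        Decision-value cuts of the postprocessing: the permissive mask cut
        (0 = class boundary) and the strict marker cut T.
    connectivity : {4, 8}
        Pixel connectivity of the morphological reconstruction.
    probability : bool
        Also fit a Platt-calibrated probability output on the SVM
        (postprocessing still operates on decision values).
    random_state : int
        Seed of the pixel sampler.

    Attributes
    ----------
    svm_ : fitted :class:`sklearn.svm.SVC`
    metadata_ : dict with the effective C/gamma, normalization scheme,
        feature order and seed.
    """

    def __init__(
        self,
        s: float = 5.0,
        samples_per_image: int = 20000,
        C: float = 1.0,
        gamma: float = 0.01,
        grid_search: bool = False,
        cv_folds: int = 5,
        normalization: str = "zscore",
        base_threshold: float = 0.0,
        marker_threshold: float = 0.2,
        connectivity: int = 8,
        probability: bool = False,
        random_state: int = 0,
    ) -> None:
        self.s = s
        self.samples_per_image = samples_per_image
        self.C = C
        self.gamma = gamma
        self.grid_search = grid_search
        self.cv_folds = cv_folds
        self.normalization = normalization
        self.base_threshold = base_threshold
        self.marker_threshold = marker_threshold
        self.connectivity = connectivity
        self.probability = probability
        self.random_state = random_state

    def _lineset_config(self) -> LineSetConfig:
        return LineSetConfig(s_threshold=self.s)

    def describe(self, image: IntensityImage) -> pd.DataFrame:
        """Normalized descriptor table of one image (its own statistics)."""
        table = build_descriptors(image, self._lineset_config(), IntensityFeatureConfig())
        normed, _ = normalize_descriptors(table, scheme=self.normalization)
        return normed

    def fit(self, images, ground_truths):
        """Fit on parallel sequences of images and boolean vessel maps."""
        images = list(images)
        ground_truths = [np.asarray(g, dtype=bool) for g in ground_truths]
        if len(images) != len(ground_truths) or not images:
            raise ValueError("need equally many images and ground truths")
        rng = np.random.default_rng(self.random_state)
        parts = []
        for img, truth in zip(images, ground_truths):
            table = self.describe(img)
            coords, labels = sample_training_pixels(
                img, truth, min(self.samples_per_image, len(table)), rng
            )
            pos = np.full(img.shape, -1, dtype=np.int64)
            pos[table["row"].to_numpy(), table["col"].to_numpy()] = np.arange(len(table))
            picked = table.iloc[pos[coords[:, 0], coords[:, 1]]].reset_index(drop=True)
            picked["label"] = labels
            parts.append(picked)
        training = pd.concat(parts, ignore_index=True)
        cfg = TrainingConfig(
            samples_per_image=self.samples_per_image,
            rng_seed=self.random_state,
            svm_c=self.C,
            rbf_bandwidth=self.gamma,
            cv_folds=self.cv_folds,
        )
        self.svm_ = train(
            training, cfg, grid_search=self.grid_search, probability=self.probability
        )
        self.n_features_in_ = len(COMPONENT_NAMES)
        self.metadata_ = {
            "C": float(self.svm_.C),
            "gamma": float(self.svm_.gamma),
            "normalization": self.normalization,
            "feature_order": list(COMPONENT_NAMES),
            "random_state": self.random_state,
            "n_training_pixels": len(training),
        }
        return self

    def decision_function(self, image: IntensityImage) -> ScoreImage:
        """Score image of SVM decision values on the FOV."""
        self._check_fitted()
        return score_image(self.svm_, self.describe(image), image.shape)

    def predict(self, image: IntensityImage):
        """Final binary segmentation of one image (after postprocessing)."""
        from .postprocess import PostprocessConfig, postprocess

        self._check_fitted()
        cfg = PostprocessConfig(
            base_threshold=self.base_threshold,
            marker_threshold=self.marker_threshold,
            connectivity=self.connectivity,
        )
        return postprocess(self.decision_function(image), cfg, model_id=self._model_id())

    def predict_proba_image(self, image: IntensityImage) -> np.ndarray:
        """Platt-calibrated vessel probability per FOV pixel (NaN off FOV).

        Requires ``probability=True`` at fit time.
        """
        self._check_fitted()
        if not self.svm_.probability:
            raise ValueError("fit with probability=True to get probabilities")
        table = self.describe(image)
        X = table[COMPONENT_NAMES].to_numpy(dtype=np.float64)
        p = self.svm_.predict_proba(X)[:, list(self.svm_.classes_).index(True)]
        out = np.full(image.shape, np.nan)
        out[table["row"].to_numpy(), table["col"].to_numpy()] = p
        return out

    def save(self, path) -> None:
        self._check_fitted()
        joblib.dump({"params": self.get_params(), "svm": self.svm_,
                     "metadata": self.metadata_}, path)

    @classmethod
    def load(cls, path) -> "VesselSegmenter":
        payload = joblib.load(path)
        est = cls(**payload["params"])
        est.svm_ = payload["svm"]
        est.metadata_ = payload["metadata"]
        est.n_features_in_ = len(COMPONENT_NAMES)
        return est

    def _model_id(self) -> str:
        m = self.metadata_
        return f"svm-rbf C={m['C']} gamma={m['gamma']} seed={m['random_state']}"

    def _check_fitted(self) -> None:
        if not hasattr(self, "svm_"):
            raise ValueError("estimator is not fitted; call fit first")
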