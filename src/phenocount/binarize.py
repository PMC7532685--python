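"""Grayscale preprocessing, thresholding and cell-splitting.

The binarisation chain mirrors a standard fluorescent-channel pipeline:

1. collapse RGB input to luminance,
2. bilateral denoising and contrast-limited adaptive histogram
   equalisation (CLAHE),
3. threshold selection by one of 16 histogram methods (Triangle by
   default), optionally modulated by a learned correction factor ``c`` so
   that the final threshold is ``T = c * T_raw``,
4. binarisation with the convention pixel ``>= T`` -> foreground,
5. watershed splitting of touching cells on the distance transform.

The correction factor is regressed on the 166-dimensional image
descriptor (:mod:`phenocount.features`).  Training labels are obtained by
grid search: for each training image with a known truth mask, ``c*`` is
the grid value in [0.2, 3.0] (step 0.05) minimising the pixelwise
disagreement between the corrected Triangle binarisation and the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.color import rgb2gray
from skimage.exposure import equalize_adapthist
from skimage.feature import peak_local_max
from skimage.restoration import denoise_bilateral
from skimage.segmentation import watershed

from . import features as feat
from .features import FeatureVector, _as_uint8_view
from .thresholds import THRESHOLD_METHODS, image_histogram, threshold_histogram

CORRECTION_GRID = np.round(np.arange(0.2, 3.0 + 1e-9, 0.05), 10)


# --------------------------------------------------------------- preprocessing

def to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luminance; grayscale input passes through.

    RGB input is converted with the Rec. 709 luminance weights
    (0.2125 R + 0.7154 G + 0.0721 B) and returned as float in [0, 1].
    """
    a = np.asarray(image)
    if a.ndim == 2:
        return a
    if a.ndim == 3 and a.shape[2] == 3:
        return rgb2gray(a)
    raise ValueError(f"expected a 2-D or 3-channel image, got shape {a.shape}")


def _to_float01(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if np.issubdtype(a.dtype, np.integer):
        scale = 255.0 if a.max(initial=0) <= 255 else 65535.0
        return a.astype(np.float64) / scale
    return np.clip(a.astype(np.float64), 0.0, 1.0)


def denoise(img: np.ndarray, spatial_sigma: float = 3.0, range_sigma: float = 0.1) -> np.ndarray:
    """Edge-preserving bilateral smoothing.

    ``range_sigma`` is expressed as a fraction of the dynamic range.
    """
    if spatial_sigma <= 0 or range_sigma <= 0:
        raise ValueError("bilateral sigmas must be positive")
    a = _to_float01(img)
    if a.max() == a.min():
        return a.copy()
    return denoise_bilateral(a, sigma_color=range_sigma, sigma_spatial=spatial_sigma)


def clahe(img: np.ndarray, tiles: int = 8, clip_limit: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a tiles x tiles grid."""
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    a = _to_float01(img)
    if a.shape[0] < tiles or a.shape[1] < tiles:
        raise ValueError(f"image {a.shape} smaller than the {tiles}x{tiles} tile grid")
    if a.max() == a.min():
        return a.copy()
    kernel = (max(a.shape[0] // tiles, 1), max(a.shape[1] // tiles, 1))
    return equalize_adapthist(a, kernel_size=kernel, clip_limit=clip_limit)


def preprocess(img: np.ndarray, spatial_sigma: float = 3.0, range_sigma: float = 0.1,
               tiles: int = 8, clip_limit: float = 0.01) -> np.ndarray:
    """Denoise then contrast-enhance one channel (the step-2 chain)."""
    return clahe(denoise(to_gray(img), spatial_sigma, range_sigma), tiles, clip_limit)


# --------------------------------------------------------------- thresholding

def _bin_to_intensity(t_bin: int, img: np.ndarray) -> float:
    a = np.asarray(img)
    if a.dtype == np.uint8:
        return float(t_bin)
    if np.issubdtype(a.dtype, np.integer):
        return float(t_bin) * 257.0
    return t_bin / 255.0


def threshold(img: np.ndarray, method: str = "triangle") -> float:
    """Threshold intensity for ``img`` in the image's own units."""
    t_bin = threshold_histogram(image_histogram(img), method)
    return _bin_to_intensity(t_bin, img)


@dataclass(frozen=True)
class ThresholdDecision:
    """A thresholding outcome: ``final_threshold = correction_factor * raw``, clipped."""

    method: str
    raw_threshold: float
    correction_factor: float = 1.0
    final_threshold: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.correction_factor <= 0:
            raise ValueError("correction factor must be positive")
        if self.final_threshold is None:
            object.__setattr__(
                self, "final_threshold", self.correction_factor * self.raw_threshold
            )


def decide_threshold(img: np.ndarray, method: str = "triangle",
                     model: "CorrectionModel | None" = None) -> ThresholdDecision:
    """Raw threshold plus (optional) model-predicted correction factor."""
    raw = threshold(img, method)
    c = 1.0
    if model is not None:
        c = predict_correction_factor(feat.extract_features(img), model)
    upper = _bin_to_intensity(255, img)
    final = float(np.clip(c * raw, 0.0, upper))
    return ThresholdDecision(method, raw, c, final)


def binarize(img: np.ndarray, T: float) -> np.ndarray:
    """Binary foreground mask: pixel ``>= T`` is foreground."""
    return np.asarray(img) >= T


# --------------------------------------------------------------- correction model

_REGRESSORS = {
    "random_forest": lambda seed: __import__("sklearn.ensemble", fromlist=["x"]).RandomForestRegressor(
        n_estimators=200, random_state=seed, n_jobs=1
    ),
    "boosting": lambda seed: __import__("sklearn.ensemble", fromlist=["x"]).GradientBoostingRegressor(
        random_state=seed
    ),
    "linear": lambda seed: __import__("sklearn.linear_model", fromlist=["x"]).LinearRegression(),
    "svm_rbf": lambda seed: __import__("sklearn.svm", fromlist=["x"]).SVR(),
    "gpr": lambda seed: __import__("sklearn.gaussian_process", fromlist=["x"]).GaussianProcessRegressor(
        random_state=seed
    ),
}


@dataclass
class CorrectionModel:
    """A fitted regressor mapping image features to a Triangle correction factor."""

    kind: str
    estimator: object
    grid_lo: float = float(CORRECTION_GRID[0])
    grid_hi: float = float(CORRECTION_GRID[-1])
    n_train: int = 0
    seed: int = 0
    rmse_test: float = float("nan")
    mae_test: float = float("nan")
    baseline_mae_test: float = float("nan")
    fitted: bool = False


def optimal_correction_factor(img: np.ndarray, truth_mask: np.ndarray,
                              method: str = "triangle",
                              grid: np.ndarray = CORRECTION_GRID) -> float:
    """Grid value c minimising disagreement of ``img >= c*T_raw`` with the truth.

    Evaluated exactly via cumulative histograms of intensities inside and
    outside the truth mask; ties break toward the smaller factor.
    """
    u8 = _as_uint8_view(img)
    truth = np.asarray(truth_mask, dtype=bool)
    if truth.shape != u8.shape:
        raise ValueError("image and truth mask shapes differ")
    raw_bin = threshold_histogram(image_histogram(img), method)
    h_in = np.bincount(u8[truth].ravel(), minlength=256)
    h_out = np.bincount(u8[~truth].ravel(), minlength=256)
    cum_in = np.concatenate([[0], np.cumsum(h_in)])    # pixels with value < t
    cum_out = np.concatenate([[0], np.cumsum(h_out)])
    best_c, best_err = None, None
    for c in grid:
        t = int(np.clip(np.ceil(c * raw_bin), 0, 256))
        err = cum_in[t] + (cum_out[256] - cum_out[t])  # fg misses + bg hits
        if best_err is None or err < best_err:
            best_c, best_err = float(c), int(err)
    return best_c


def train_correction_model(fixtures: Sequence[tuple[np.ndarray, np.ndarray]],
                           kind: str = "random_forest", seed: int = 0,
                           method: str = "triangle") -> CorrectionModel:
    """Fit a correction-factor regressor on (image, truth mask) fixtures.

    Uses an 80:20 train/test split; reports test RMSE/MAE and the MAE of
    the uncorrected (c = 1) baseline on the same split.
    """
    from sklearn.model_selection import train_test_split

    if kind not in _REGRESSORS:
        raise KeyError(f"unknown regressor kind {kind!r}")
    X, y = [], []
    for img, truth in fixtures:
        truth = np.asarray(truth, dtype=bool)
        if truth.all() or not truth.any():
            warnings.warn("skipping degenerate fixture (uniform truth mask)")
            continue
        X.append(feat.extract_features(img).values)
        y.append(optimal_correction_factor(img, truth, method=method))
    if len(X) < 50:
        raise ValueError(f"need at least 50 usable fixtures, got {len(X)}")
    X = np.vstack(X)
    y = np.asarray(y)
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2, random_state=seed)
    est = _REGRESSORS[kind](seed)
    est.fit(Xtr, ytr)
    pred = np.clip(est.predict(Xte), CORRECTION_GRID[0], CORRECTION_GRID[-1])
    model = CorrectionModel(
        kind=kind, estimator=est, n_train=len(ytr), seed=seed,
        rmse_test=float(np.sqrt(np.mean((pred - yte) ** 2))),
        mae_test=float(np.mean(np.abs(pred - yte))),
        baseline_mae_test=float(np.mean(np.abs(1.0 - yte))),
        fitted=True,
    )
    return model


def predict_correction_factor(features: FeatureVector | np.ndarray,
                              model: CorrectionModel) -> float:
    """Finite positive correction factor, clipped to the training grid range."""
    if not model.fitted:
        raise ValueError("correction model is not fitted")
    v = features.values if isinstance(features, FeatureVector) else np.asarray(features, float)
    c = float(model.estimator.predict(v.reshape(1, -1))[0])
    if not np.isfinite(c):
        raise ValueError("regressor produced a non-finite correction factor")
    return float(np.clip(c, model.grid_lo, model.grid_hi))


# --------------------------------------------------------------- watershed

def watershed_split(mask: np.ndarray, min_distance: int = 5,
                    smoothing_sigma: float = 1.0) -> np.ndarray:
    """Split touching foreground blobs at distance-transform ridges.

    Markers are local maxima of the (slightly smoothed) Euclidean distance
    transform; the background keeps label 0.  An empty mask yields an
    all-zero labelling.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    dsm = ndi.gaussian_filter(dist, smoothing_sigma)
    coords = peak_local_max(dsm, min_distance=min_distance, labels=mask,
                            exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:  # tiny blobs can lack a detected peak
        lab, _ = ndi.label(mask)
        return lab.astype(np.int32)
    labels = watershed(-dsm, markers, mask=mask)
    # any component missed by the peak detector keeps its own label
    missed = mask & (labels == 0)
    if missed.any():
        extra, n = ndi.label(missed)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return labels.astype(np.int32)
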