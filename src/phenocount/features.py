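"""Image descriptors for threshold correction and image forensics.

Every grayscale image is summarised by a fixed, ordered 166-dimensional
feature vector::

    [ 7 whole-image histogram statistics |
      9 x 7 per-block histogram statistics (3 x 3 partition, row-major) |
      24 x 4 Gabor moments (4 wavelengths x 6 orientations, scale-major) ]

The seven histogram statistics are computed on the normalised 256-bin
intensity histogram p(i):

* mean        mu = sum i * p(i)
* sd          sigma = sqrt(sum (i - mu)^2 p(i))
* skewness    third standardised moment (0 for zero-variance histograms)
* kurtosis    fourth standardised moment, non-excess (0 for zero variance)
* energy      sum p(i)^2
* entropy     -sum p(i) log2 p(i), with 0 log 0 := 0
* smoothness  1 - 1/(1 + sigma_n^2), sigma_n the SD of intensities
              rescaled to [0, 1]

The Gabor bank uses wavelengths {2.0, 2.5, 3.0, 3.5} px/cycle and
orientations {0, 60, ..., 300} degrees; the mean, variance, skewness and
kurtosis of each magnitude response are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gabor_kernel

N_FEATURES = 166
GABOR_WAVELENGTHS = (2.0, 2.5, 3.0, 3.5)
GABOR_ORIENTATIONS_DEG = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
_STAT_NAMES = ("mean", "sd", "skewness", "kurtosis", "energy", "entropy", "smoothness")
_MOMENT_NAMES = ("mean", "var", "skewness", "kurtosis")

LAYOUT_VERSION = "hist7+block63+gabor96/v1"


def feature_names() -> list[str]:
    """Stable column names for the 166 features, in vector order."""
    names = [f"hist_{s}" for s in _STAT_NAMES]
    for b in range(9):
        names += [f"block{b}_{s}" for s in _STAT_NAMES]
    for lam in GABOR_WAVELENGTHS:
        for deg in GABOR_ORIENTATIONS_DEG:
            names += [f"gabor_l{lam}_t{int(deg)}_{m}" for m in _MOMENT_NAMES]
    return names


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 166-dimensional image descriptor."""

    values: np.ndarray
    layout_version: str = LAYOUT_VERSION

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return N_FEATURES


def _as_uint8_view(img: np.ndarray) -> np.ndarray:
    """Map an image to the 8-bit analysis range [0, 255].

    Float images are assumed to live in [0, 1]; 16-bit integer images are
    rescaled by 257 so that histograms always use 256 bins.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if a.dtype == np.uint8:
        return a
    if np.issubdtype(a.dtype, np.integer):
        if a.max(initial=0) > 255:
            return (a.astype(np.float64) / 257.0).round().astype(np.uint8)
        return a.astype(np.uint8)
    return np.clip(np.asarray(a, dtype=np.float64) * 255.0, 0, 255).round().astype(np.uint8)


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, var, skew, kurt) with the zero-variance convention skew=kurt=0."""
    x = np.asarray(x, dtype=np.float64).ravel()
    mu = float(x.mean())
    var = float(x.var())
    if var <= 0:
        return mu, 0.0, 0.0, 0.0
    z = (x - mu) / np.sqrt(var)
    return mu, var, float(np.mean(z**3)), float(np.mean(z**4))


def histogram_stats(img: np.ndarray) -> np.ndarray:
    """Seven statistics of the normalised 256-bin intensity histogram."""
    u8 = _as_uint8_view(img)
    counts = np.bincount(u8.ravel(), minlength=256).astype(np.float64)
    p = counts / counts.sum()
    i = np.arange(256, dtype=np.float64)
    mu = float(np.sum(i * p))
    var = float(np.sum((i - mu) ** 2 * p))
    sd = np.sqrt(var)
    if var > 0:
        z3 = float(np.sum(((i - mu) / sd) ** 3 * p))
        z4 = float(np.sum(((i - mu) / sd) ** 4 * p))
    else:
        z3 = z4 = 0.0
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    sigma_n2 = var / 255.0**2
    smoothness = 1.0 - 1.0 / (1.0 + sigma_n2)
    return np.array([mu, sd, z3, z4, energy, entropy, smoothness])


def _block_slices(n: int) -> list[slice]:
    # np.array_split semantics: remainder pixels go to the first blocks,
    # e.g. 10 -> (4, 3, 3).
    sizes = [n // 3 + (1 if k < n % 3 else 0) for k in range(3)]
    edges = np.cumsum([0] + sizes)
    return [slice(edges[k], edges[k + 1]) for k in range(3)]


def block_stats(img: np.ndarray) -> np.ndarray:
    """63 values: the seven histogram statistics on each 3x3 block, row-major."""
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for block statistics")
    rows = _block_slices(a.shape[0])
    cols = _block_slices(a.shape[1])
    out = []
    for r in rows:
        for c in cols:
            out.append(histogram_stats(a[r, c]))
    return np.concatenate(out)


class _GaborBank:
    """Cached Gabor kernels and their FFTs, keyed by image shape.

    Kernel parameters follow the convention wavelength = px/cycle,
    sigma_x = 0.56 * wavelength, aspect ratio 0.5 (sigma_y = 2 sigma_x),
    truncated at 3 sigma.  Responses are computed by circular (FFT)
    convolution, which is exact up to the periodic boundary.
    """

    def __init__(self):
        self.kernels = []
        for lam in GABOR_WAVELENGTHS:
            for deg in GABOR_ORIENTATIONS_DEG:
                k = gabor_kernel(
                    frequency=1.0 / lam,
                    theta=np.deg2rad(deg),
                    sigma_x=0.56 * lam,
                    sigma_y=1.12 * lam,
                    n_stds=3,
                )
                self.kernels.append(np.asarray(k))
        self.max_kernel_side = max(max(k.shape) for k in self.kernels)
        self._fft_cache: dict[tuple[int, int], list[np.ndarray]] = {}

    def _kernel_ffts(self, shape: tuple[int, int]) -> list[np.ndarray]:
        if shape not in self._fft_cache:
            ffts = []
            for k in self.kernels:
                pad = np.zeros(shape, dtype=complex)
                h, w = k.shape
                pad[:h, :w] = k
                # centre the kernel so the response is not translated
                pad = np.roll(pad, (-(h // 2), -(w // 2)), axis=(0, 1))
                ffts.append(np.fft.fft2(pad))
            if len(self._fft_cache) > 8:
                self._fft_cache.clear()
            self._fft_cache[shape] = ffts
        return self._fft_cache[shape]

    def magnitude_responses(self, img: np.ndarray):
        f = np.fft.fft2(img.astype(np.float64))
        for kf in self._kernel_ffts(img.shape):
            yield np.abs(np.fft.ifft2(f * kf))


_BANK: _GaborBank | None = None


def _bank() -> _GaborBank:
    global _BANK
    if _BANK is None:
        _BANK = _GaborBank()
    return _BANK


def gabor_features(img: np.ndarray) -> np.ndarray:
    """96 values: 4 moments of each of the 24 Gabor magnitude responses.

    Order is wavelength-major, then orientation, then moment.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    bank = _bank()
    if min(a.shape) < bank.max_kernel_side:
        raise ValueError(
            f"image {a.shape} smaller than the largest Gabor kernel "
            f"({bank.max_kernel_side} px)"
        )
    if a.dtype != np.float64 or a.max(initial=0.0) > 1.0:
        a = _as_uint8_view(a) / 255.0
    out = np.empty(96)
    for j, resp in enumerate(bank.magnitude_responses(a)):
        out[4 * j : 4 * j + 4] = _moments(resp)
    return out


def extract_features(img: np.ndarray) -> FeatureVector:
    """Concatenated [7 | 63 | 96] descriptor of one grayscale image."""
    return FeatureVector(
        np.concatenate([histogram_stats(img), block_stats(img), gabor_features(img)])
    )


def feature_matrix(images) -> np.ndarray:
    """Stack feature vectors for an iterable of images into an (n, 166) array."""
    return np.vstack([extract_features(im).values for im in images])


def write_feature_csv(path, images=None, matrix: np.ndarray | None = None) -> None:
    """Write a feature matrix (one row per image) as CSV with stable headers."""
    import pandas as pd

    if matrix is None:
        if images is None:
            raise ValueError("provide images or a precomputed matrix")
        matrix = feature_matrix(images)
    pd.DataFrame(np.atleast_2d(matrix), columns=feature_names()).to_csv(path, index=False)
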