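"""Sixteen gray-level thresholding methods on 256-bin histograms.

All methods operate on a 256-bin intensity histogram (16-bit images are
analysed on a rescaled 256-bin view) and return an integer threshold bin
``T`` under the convention that pixels ``>= T`` are foreground.  Ties in a
method's objective are broken toward the lower intensity.

Most methods are classical histogram-partition criteria: a split ``s``
puts bins ``0..s`` in the background and ``s+1..255`` in the foreground,
and the returned threshold is ``s + 1``.  The registry
:data:`THRESHOLD_METHODS` exposes every method behind one interface.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "THRESHOLD_METHODS",
    "DegenerateHistogramError",
    "threshold_histogram",
    "image_histogram",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram cannot support the requested method."""


def image_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of an image on its 8-bit analysis view."""
    from .features import _as_uint8_view

    return np.bincount(_as_uint8_view(img).ravel(), minlength=256).astype(np.float64)


def _valid_splits(counts: np.ndarray) -> np.ndarray:
    """Splits s for which both background (<= s) and foreground (> s) are non-empty."""
    c = np.cumsum(counts)
    total = c[-1]
    return np.nonzero((c[:-1] > 0) & (c[:-1] < total))[0]


def _single_level(counts: np.ndarray) -> int | None:
    nz = np.nonzero(counts)[0]
    return int(nz[0]) if len(nz) == 1 else None


def _argbest(values: np.ndarray, splits: np.ndarray, maximize: bool) -> int:
    v = np.asarray(values, dtype=float)
    v = np.where(np.isfinite(v), v, -np.inf if maximize else np.inf)
    idx = int(np.argmax(v) if maximize else np.argmin(v))  # first index wins ties
    return int(splits[idx]) + 1


def _class_stats(counts: np.ndarray):
    """Cumulative weight/mean/variance of the two classes at every split s."""
    p = counts / counts.sum()
    i = np.arange(256, dtype=np.float64)
    w = np.cumsum(p)
    m = np.cumsum(i * p)
    m2 = np.cumsum(i * i * p)
    w0 = w[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m[:-1] / w0, 0.0)
        mu1 = np.where(w1 > 0, (m[-1] - m[:-1]) / w1, 0.0)
        var0 = np.where(w0 > 0, m2[:-1] / w0 - mu0**2, 0.0)
        var1 = np.where(w1 > 0, (m2[-1] - m2[:-1]) / w1 - mu1**2, 0.0)
    return w0, w1, mu0, mu1, np.maximum(var0, 0.0), np.maximum(var1, 0.0)


# ---------------------------------------------------------------- simple

def mean_threshold(counts: np.ndarray) -> int:
    """Average of grey levels, rounded to the nearest bin."""
    p = counts / counts.sum()
    return int(round(float(np.sum(np.arange(256) * p))))


def percentile_threshold(counts: np.ndarray, foreground_fraction: float = 0.5) -> int:
    """Threshold making the brighter ``foreground_fraction`` of pixels foreground.

    Returns the (1 - foreground_fraction) quantile of the pixel values
    (the median for the default), so pixels at and above it are foreground.
    """
    cum = np.cumsum(counts)
    return int(np.searchsorted(cum, (1.0 - foreground_fraction) * cum[-1]))


def isodata_threshold(counts: np.ndarray) -> int:
    """Iterative-selection fixed point: T = (mean background + mean foreground)/2.

    Computed exactly as the split whose midpoint of class means is closest
    to the split itself (the iteration's stationary point).
    """
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    w0, w1, mu0, mu1, _, _ = _class_stats(counts)
    mid = (mu0[splits] + mu1[splits]) / 2.0
    # threshold candidate T = s + 1; stationary when T is nearest to mid
    return _argbest(-np.abs(splits + 1 - mid), splits, maximize=True)


# ---------------------------------------------------------------- variance / error

def otsu_threshold(counts: np.ndarray) -> int:
    """Maximise between-class variance (equivalently minimise intra-class)."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    w0, w1, mu0, mu1, _, _ = _class_stats(counts)
    bcv = (w0 * w1 * (mu0 - mu1) ** 2)[splits]
    return _argbest(bcv, splits, maximize=True)


def min_error_threshold(counts: np.ndarray) -> int:
    """Kittler-Illingworth minimum classification error under Gaussian classes."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    w0, w1, mu0, mu1, var0, var1 = _class_stats(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = 1.0 + w0 * np.log(var0) + w1 * np.log(var1) - 2.0 * (
            w0 * np.log(w0) + w1 * np.log(w1)
        )
    # single-level classes have exactly zero variance; require a variance
    # clearly above float noise before taking its logarithm
    J = np.where((var0 > 1e-6) & (var1 > 1e-6), J, np.inf)
    if not np.any(np.isfinite(J[splits])):
        # classes are single-valued everywhere; fall back to the variance criterion
        return otsu_threshold(counts)
    return _argbest(J[splits], splits, maximize=False)


# ---------------------------------------------------------------- entropies

def _region_entropies(counts: np.ndarray):
    p = counts / counts.sum()
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H_cum = np.cumsum(plogp)
    H0 = H_cum[:-1]
    H1 = H_cum[-1] - H_cum[:-1]
    return p, P0, P1, H0, H1


def max_entropy_threshold(counts: np.ndarray) -> int:
    """Kapur's maximum sum of background and foreground Shannon entropies."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    p, P0, P1, H0, H1 = _region_entropies(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.log(P0) - H0 / P0 + np.log(P1) - H1 / P1
    return _argbest(crit[splits], splits, maximize=True)


def renyi_entropy_threshold(counts: np.ndarray, alpha: float = 2.0) -> int:
    """Kapur's scheme with the order-``alpha`` Renyi entropy (default 2)."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    p = counts / counts.sum()
    pa = np.cumsum(p**alpha)
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    S0 = pa[:-1]
    S1 = pa[-1] - pa[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = (np.log(S0 / P0**alpha) + np.log(S1 / P1**alpha)) / (1.0 - alpha)
    return _argbest(crit[splits], splits, maximize=True)


def yen_threshold(counts: np.ndarray) -> int:
    """Yen's maximum correlation criterion."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    p = counts / counts.sum()
    p2 = np.cumsum(p**2)
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    S0 = p2[:-1]
    S1 = p2[-1] - p2[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(S0 * S1) + 2.0 * np.log(P0 * P1)
    return _argbest(crit[splits], splits, maximize=True)


def li_threshold(counts: np.ndarray) -> int:
    """Li's minimum cross entropy between the image and its binarisation.

    The cross entropy is evaluated exactly at every split (intensities are
    shifted by +1 so logarithms stay finite at gray level 0).
    """
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    i = np.arange(256, dtype=np.float64) + 1.0
    h = counts
    w = np.cumsum(h)
    a = np.cumsum(i * h)
    W0, A0 = w[:-1], a[:-1]
    W1, A1 = w[-1] - w[:-1], a[-1] - a[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = A0 / W0
        mu1 = A1 / W1
        # constant terms sum(i h ln i) omitted; minimise -(A0 ln mu0 + A1 ln mu1)
        ce = -(A0 * np.log(mu0) + A1 * np.log(mu1))
    return _argbest(ce[splits], splits, maximize=False)


# ---------------------------------------------------------------- fuzzy

def _huang_fuzziness(counts: np.ndarray, splits: np.ndarray) -> np.ndarray:
    """Huang & Wang fuzziness for each split, looped per candidate."""
    nz = np.nonzero(counts)[0]
    C = float(max(nz[-1] - nz[0], 1))
    i = np.arange(256, dtype=np.float64)
    _, _, mu0, mu1, _, _ = _class_stats(counts)
    out = np.empty(len(splits))
    for j, s in enumerate(splits):
        mu = np.where(i <= s, mu0[s], mu1[s])
        u = 1.0 / (1.0 + np.abs(i - mu) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            shannon = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        shannon = np.where((u <= 0) | (u >= 1), 0.0, shannon)
        out[j] = float(np.sum(counts * shannon))
    return out


def huang_threshold(counts: np.ndarray) -> int:
    """Minimise Huang & Wang's measure of fuzziness."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    return _argbest(_huang_fuzziness(counts, splits), splits, maximize=False)


def huang2_threshold(counts: np.ndarray) -> int:
    """Huang objective evaluated on a broadcast (fully vectorised) path.

    Same objective and result as :func:`huang_threshold`; this variant
    trades memory for speed, which pays off on 16-bit analysis views.
    """
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    nz = np.nonzero(counts)[0]
    C = float(max(nz[-1] - nz[0], 1))
    i = np.arange(256, dtype=np.float64)
    _, _, mu0, mu1, _, _ = _class_stats(counts)
    below = i[None, :] <= splits[:, None]
    mu = np.where(below, mu0[splits][:, None], mu1[splits][:, None])
    u = 1.0 / (1.0 + np.abs(i[None, :] - mu) / C)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
    shannon = np.where((u <= 0) | (u >= 1), 0.0, shannon)
    # same pairwise summation order as the per-split path, so exact
    # objective plateaus tie-break identically
    fuzz = np.sum(shannon * counts[None, :], axis=1)
    return _argbest(fuzz, splits, maximize=False)


def shanbhag_threshold(counts: np.ndarray) -> int:
    """Shanbhag's fuzzy-set information measure, |H_background - H_foreground|."""
    s = _single_level(counts)
    if s is not None:
        return s
    splits = _valid_splits(counts)
    p = counts / counts.sum()
    cum = np.cumsum(p)
    crit = np.empty(len(splits))
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, t in enumerate(splits):
            P0 = cum[t]
            P1 = 1.0 - P0
            if P0 <= 0 or P1 <= 0:
                crit[j] = np.inf
                continue
            # zero-weight bins contribute nothing (0 log 0 := 0)
            ih = np.arange(1, t + 1)
            ih = ih[p[ih] > 0]
            ent_back = -np.sum(p[ih] * np.log1p(-cum[ih - 1] / P0)) / P0 if len(ih) else 0.0
            ih = np.arange(t + 1, 255)
            ih = ih[p[ih] > 0]
            ent_obj = -np.sum(p[ih] * np.log1p(-(1.0 - cum[ih]) / P1)) / P1 if len(ih) else 0.0
            v = abs(ent_back - ent_obj)
            crit[j] = v if np.isfinite(v) else np.inf
    return _argbest(crit, splits, maximize=False)


# ---------------------------------------------------------------- geometric / moments

def triangle_threshold(counts: np.ndarray) -> int:
    """Farthest point from the chord joining the histogram peak to its tail end."""
    s = _single_level(counts)
    if s is not None:
        return s
    nz = np.nonzero(counts)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(counts))  # first maximal bin
    # chord runs toward the longer tail
    if hi - peak >= peak - lo:
        b0, b1 = peak, hi
    else:
        b0, b1 = peak, lo
    if b0 == b1:
        return peak
    xs = np.arange(min(b0, b1), max(b0, b1) + 1)
    # perpendicular distance of (x, h(x)) to the line through the two endpoints
    x1, y1 = b0, float(counts[b0])
    x2, y2 = b1, float(counts[b1])
    num = np.abs((y2 - y1) * xs - (x2 - x1) * counts[xs] + x2 * y1 - y2 * x1)
    best = int(xs[np.argmax(num)])
    # pixels at and above the chosen level are foreground when the tail is bright
    return best if b1 > b0 else best


def moments_threshold(counts: np.ndarray) -> int:
    """Tsai's moment-preserving threshold.

    Finds the two-level image with identical first three moments and picks
    the threshold at the corresponding population fraction.
    """
    s = _single_level(counts)
    if s is not None:
        return s
    p = counts / counts.sum()
    i = np.arange(256, dtype=np.float64)
    m1 = float(np.sum(i * p))
    m2 = float(np.sum(i**2 * p))
    m3 = float(np.sum(i**3 * p))
    cd = m2 - m1**2
    if cd <= 0:
        return int(round(m1))
    c0 = (-m2**2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1**2 - 4.0 * c0
    if disc < 0:
        return int(round(m1))
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return int(round(m1))
    pd = (z1 - m1) / (z1 - z0)  # fraction of pixels at the darker level
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, pd) + 1)


# ---------------------------------------------------------------- bimodal smoothing

def _smooth_until_bimodal(counts: np.ndarray, max_iter: int = 10_000) -> np.ndarray:
    h = counts.astype(np.float64).copy()

    def n_maxima(y):
        left = np.r_[-np.inf, y[:-1]]
        right = np.r_[y[1:], -np.inf]
        return int(np.sum((y > left) & (y > right))), np.nonzero((y > left) & (y > right))[0]

    for _ in range(max_iter):
        n, _peaks = n_maxima(h)
        if n == 2:
            return h
        if n < 2:
            raise DegenerateHistogramError(
                "histogram cannot be smoothed to two modes (fewer than two maxima)"
            )
        # 3-tap moving mean with replicated ends
        h = (np.r_[h[0], h[:-1]] + h + np.r_[h[1:], h[-1]]) / 3.0
    raise DegenerateHistogramError("histogram failed to become bimodal within the budget")


def _two_peaks(counts: np.ndarray):
    h = _smooth_until_bimodal(counts)
    left = np.r_[-np.inf, h[:-1]]
    right = np.r_[h[1:], -np.inf]
    peaks = np.nonzero((h > left) & (h > right))[0]
    return h, int(peaks[0]), int(peaks[1])


def intermodes_threshold(counts: np.ndarray) -> int:
    """Midpoint of the two modes after iterative histogram smoothing."""
    _, p1, p2 = _two_peaks(counts)
    return int(round((p1 + p2) / 2.0))


def minimum_threshold(counts: np.ndarray) -> int:
    """Deepest valley between the two modes after iterative smoothing."""
    h, p1, p2 = _two_peaks(counts)
    valley = np.arange(p1 + 1, p2)
    if len(valley) == 0:
        return p2
    return int(valley[np.argmin(h[valley])])


THRESHOLD_METHODS = {
    "huang": huang_threshold,
    "huang2": huang2_threshold,
    "intermodes": intermodes_threshold,
    "iterative_selection": isodata_threshold,
    "li": li_threshold,
    "max_entropy": max_entropy_threshold,
    "mean": mean_threshold,
    "min_error": min_error_threshold,
    "minimum": minimum_threshold,
    "moments": moments_threshold,
    "otsu": otsu_threshold,
    "percentile": percentile_threshold,
    "renyi_entropy": renyi_entropy_threshold,
    "shanbhag": shanbhag_threshold,
    "triangle": triangle_threshold,
    "yen": yen_threshold,
}


def threshold_histogram(counts: np.ndarray, method: str) -> int:
    """Dispatch a 256-bin histogram to one of the 16 registered methods."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if counts.sum() <= 0:
        raise DegenerateHistogramError("empty histogram")
    if method not in THRESHOLD_METHODS:
        raise KeyError(f"unknown thresholding method {method!r}; "
                       f"choose from {sorted(THRESHOLD_METHODS)}")
    return int(THRESHOLD_METHODS[method](counts))
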