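"""Shared fixtures and slow, independent oracle implementations.

The oracle functions here deliberately re-derive each quantity with plain
Python loops straight from its defining formula, independent of the
vectorised implementations they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenocount import simgen as sg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_fov(seed: int, size: int = 128, n_markers: int = 1,
              mix: dict | None = None, **spec_kw):
    """One small FOV for unit tests."""
    mix = mix if mix is not None else {"P2": 2, "P1": 1}
    ids = tuple(range(n_markers))
    spec = sg.FOVSpec(width=size, height=size, n_marker_channels=n_markers,
                      phenotype_mix=mix, seed=seed, channel_ids=ids, **spec_kw)
    return sg.generate_fov(spec)


@pytest.fixture(scope="session")
def clean_nucleus_images():
    """60 clean small nucleus channels (session-cached for forensics tests)."""
    return [small_fov(1000 + s)[0].nucleus for s in range(60)]


# ------------------------------------------------------------------ threshold oracles

def _split_stats(counts, s):
    w0 = sum(counts[: s + 1])
    w1 = sum(counts[s + 1:])
    m0 = sum(i * counts[i] for i in range(s + 1)) / w0 if w0 else 0.0
    m1 = sum(i * counts[i] for i in range(s + 1, 256)) / w1 if w1 else 0.0
    return w0, w1, m0, m1


def _valid_splits(counts):
    total = sum(counts)
    c = 0
    out = []
    for s in range(255):
        c += counts[s]
        if 0 < c < total:
            out.append(s)
    return out


def brute_force_threshold(counts, objective, maximize):
    """Exhaustive search of an objective over all 256 candidate splits."""
    best_s, best_v = None, None
    for s in _valid_splits(counts):
        v = objective(counts, s)
        if v is None or not math.isfinite(v):
            continue
        better = best_v is None or (v > best_v if maximize else v < best_v)
        if better:
            best_s, best_v = s, v
    return None if best_s is None else best_s + 1


def obj_otsu(counts, s):
    w0, w1, m0, m1 = _split_stats(counts, s)
    n = sum(counts)
    return (w0 / n) * (w1 / n) * (m0 - m1) ** 2


def obj_isodata(counts, s):
    _, _, m0, m1 = _split_stats(counts, s)
    return -abs((s + 1) - (m0 + m1) / 2.0)


def obj_max_entropy(counts, s):
    n = sum(counts)
    P0 = sum(counts[: s + 1]) / n
    P1 = 1 - P0
    h0 = -sum((c / n / P0) * math.log(c / n / P0)
              for c in counts[: s + 1] if c > 0)
    h1 = -sum((c / n / P1) * math.log(c / n / P1)
              for c in counts[s + 1:] if c > 0)
    return h0 + h1


def obj_renyi2(counts, s):
    n = sum(counts)
    P0 = sum(counts[: s + 1]) / n
    P1 = 1 - P0
    s0 = sum((c / n / P0) ** 2 for c in counts[: s + 1])
    s1 = sum((c / n / P1) ** 2 for c in counts[s + 1:])
    if s0 <= 0 or s1 <= 0:
        return None
    return -math.log(s0) - math.log(s1)


def obj_yen(counts, s):
    n = sum(counts)
    P0 = sum(counts[: s + 1]) / n
    P1 = 1 - P0
    s0 = sum((c / n) ** 2 for c in counts[: s + 1])
    s1 = sum((c / n) ** 2 for c in counts[s + 1:])
    if s0 <= 0 or s1 <= 0:
        return None
    return -math.log(s0 * s1) + 2 * math.log(P0 * P1)


def obj_li(counts, s):
    a0 = sum((i + 1.0) * counts[i] for i in range(s + 1))
    a1 = sum((i + 1.0) * counts[i] for i in range(s + 1, 256))
    w0 = sum(counts[: s + 1])
    w1 = sum(counts[s + 1:])
    if w0 == 0 or w1 == 0:
        return None
    return a0 * math.log(a0 / w0) + a1 * math.log(a1 / w1)


def obj_min_error(counts, s):
    n = sum(counts)
    w0, w1, m0, m1 = _split_stats(counts, s)
    v0 = sum(counts[i] * (i - m0) ** 2 for i in range(s + 1)) / w0
    v1 = sum(counts[i] * (i - m1) ** 2 for i in range(s + 1, 256)) / w1
    if v0 <= 1e-6 or v1 <= 1e-6:
        return None
    W0, W1 = w0 / n, w1 / n
    return 1 + W0 * math.log(v0) + W1 * math.log(v1) \
        - 2 * (W0 * math.log(W0) + W1 * math.log(W1))


def obj_huang(counts, s):
    nz = [i for i in range(256) if counts[i] > 0]
    C = max(nz[-1] - nz[0], 1)
    _, _, m0, m1 = _split_stats(counts, s)
    tot = 0.0
    for i in range(256):
        if counts[i] == 0:
            continue
        mu = m0 if i <= s else m1
        u = 1.0 / (1.0 + abs(i - mu) / C)
        if 0 < u < 1:
            tot += counts[i] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
    return -tot  # maximise negative fuzziness == minimise fuzziness


def obj_shanbhag(counts, s):
    n = sum(counts)
    p = [c / n for c in counts]
    cum = np.cumsum(p)
    P0 = cum[s]
    P1 = 1 - P0
    if P0 <= 0 or P1 <= 0:
        return None
    try:
        ent_b = -sum(p[i] * math.log1p(-cum[i - 1] / P0)
                     for i in range(1, s + 1) if p[i] > 0) / P0
        ent_o = -sum(p[i] * math.log1p(-(1 - cum[i]) / P1)
                     for i in range(s + 1, 255) if p[i] > 0) / P1
    except ValueError:
        return None
    return -abs(ent_b - ent_o)


THRESHOLD_ORACLES = {
    "otsu": (obj_otsu, True),
    "iterative_selection": (obj_isodata, True),
    "max_entropy": (obj_max_entropy, True),
    "renyi_entropy": (obj_renyi2, True),
    "yen": (obj_yen, True),
    "li": (obj_li, True),   # maximising sum A ln(mean) == minimising cross entropy
    "min_error": (obj_min_error, False),
    "huang": (obj_huang, True),
    "huang2": (obj_huang, True),
    "shanbhag": (obj_shanbhag, True),
}


# ------------------------------------------------------------------ misc oracles

def histogram_stats_oracle(u8):
    """Seven histogram statistics by direct loops over the 256 bins."""
    counts = [0] * 256
    for v in u8.ravel():
        counts[int(v)] += 1
    n = sum(counts)
    p = [c / n for c in counts]
    mean = sum(i * p[i] for i in range(256))
    var = sum((i - mean) ** 2 * p[i] for i in range(256))
    sd = math.sqrt(var)
    skew = sum(((i - mean) / sd) ** 3 * p[i] for i in range(256)) if sd > 0 else 0.0
    kurt = sum(((i - mean) / sd) ** 4 * p[i] for i in range(256)) if sd > 0 else 0.0
    energy = sum(v * v for v in p)
    entropy = -sum(v * math.log2(v) for v in p if v > 0)
    smooth = 1 - 1 / (1 + var / 255.0**2)
    return np.array([mean, sd, skew, kurt, energy, entropy, smooth])


def bilateral_oracle(img, spatial_sigma, range_sigma, truncate=2.0):
    """Direct double-loop bilateral filter (small images only)."""
    h, w = img.shape
    rad = int(truncate * spatial_sigma)
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            num = den = 0.0
            for dy in range(-rad, rad + 1):
                for dx in range(-rad, rad + 1):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w):
                        continue
                    g = math.exp(-(dy * dy + dx * dx) / (2 * spatial_sigma**2))
                    r = math.exp(-(img[yy, xx] - img[y, x]) ** 2
                                 / (2 * range_sigma**2))
                    num += g * r * img[yy, xx]
                    den += g * r
            out[y, x] = num / den
    return out
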