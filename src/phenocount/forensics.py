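"""Image forensics: anomaly screening, fake-image detection, tamper localization.

Four protective layers:

1. **Anomaly screening** by robust PCA (projection-pursuit trimming plus
   a reweighted minimum-covariance-determinant step on the scores).  Each
   image's 166-feature vector is diagnosed by its score distance (SD,
   within the retained component subspace) and orthogonal distance (OD,
   residual norm) against chi-square / Wilson-Hilferty cutoffs into
   regular, good-leverage, orthogonal-outlier or bad-leverage points;
   bad-leverage points are flagged as anomalies.  Defaults k=1, alpha=0.70.
2. **Tamper detection** by a random-forest classifier on the same features.
3. **Synthetic-image detection** by a cubic-kernel SVM.
4. **Tamper localization**: per-block noise levels (PCA tail eigenvalues of
   sliding 7x7 patches) on 64x64 then 32x32 blocks, Ward-clustered with
   the cluster count (1-5) picked by the gap statistic (coarse) and the
   silhouette index (fine); the class with the fewest pixels is tampered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .features import FeatureVector, extract_features

__all__ = [
    "AnomalyModel", "PointDiagnosis", "ForensicsVerdict", "BlockNoiseMap",
    "DetectorModel", "fit_robust_pca", "diagnose", "categorize",
    "train_detector", "classify_image", "estimate_block_noise",
    "localize_tamper",
]

CATEGORIES = ("regular", "good_leverage", "orthogonal_outlier", "bad_leverage")


@dataclass
class AnomalyModel:
    k: int
    alpha: float
    center: np.ndarray          # robust centre (standardised feature space, p)
    loadings: np.ndarray        # (p, k), orthonormal columns
    eigenvalues: np.ndarray     # (k,)
    sd_cutoff: float
    od_cutoff: float
    score_location: np.ndarray  # MCD location of the scores (k,)
    score_cov: np.ndarray       # MCD covariance of the scores (k, k)
    pre_center: np.ndarray | None = None  # per-feature median of the training set
    pre_scale: np.ndarray | None = None   # per-feature robust scale (MAD)


@dataclass(frozen=True)
class PointDiagnosis:
    score_distance: float
    orthogonal_distance: float
    category: str

    @property
    def anomalous(self) -> bool:
        return self.category == "bad_leverage"


@dataclass
class ForensicsVerdict:
    synthetic: bool
    anomalous: bool
    tampered: bool
    tamper_mask: np.ndarray | None = None
    tamper_box: tuple[int, int, int, int] | None = None  # half-open (x0, x1, y0, y1)
    diagnosis: PointDiagnosis | None = None


@dataclass
class BlockNoiseMap:
    block_size: int
    noise_level: np.ndarray     # grid of per-block noise SDs, ceil(image/block)


# --------------------------------------------------------------- robust PCA

def _stahel_donoho_outlyingness(Z: np.ndarray, rng, n_directions: int = 250) -> np.ndarray:
    n = Z.shape[0]
    i = rng.integers(0, n, size=n_directions)
    j = rng.integers(0, n, size=n_directions)
    D = Z[i] - Z[j]
    norms = np.linalg.norm(D, axis=1)
    D = D[norms > 1e-12] / norms[norms > 1e-12, None]
    if len(D) == 0:
        return np.zeros(n)
    proj = Z @ D.T
    med = np.median(proj, axis=0)
    mad = np.median(np.abs(proj - med), axis=0) * 1.4826
    ok = mad > 1e-12
    if not np.any(ok):
        return np.zeros(n)
    return np.max(np.abs(proj[:, ok] - med[ok]) / mad[ok], axis=1)


def fit_robust_pca(X: np.ndarray, k: int = 1, alpha: float = 0.70,
                   seed: int = 0, n_directions: int = 250,
                   standardize: bool = True) -> AnomalyModel:
    """Robust PCA model insensitive to up to (1 - alpha) contamination.

    Features are first brought to a common scale by robust (median/MAD)
    standardisation (the 166 descriptor components have wildly different
    units).  Cutoffs: score distance from the 97.5% chi-square(k)
    quantile, orthogonal distance from the Wilson-Hilferty normal
    approximation of OD^(2/3) with robust (median/MAD) moments.
    """
    from sklearn.covariance import MinCovDet

    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    pre_center = pre_scale = None
    if standardize:
        pre_center = np.median(X, axis=0)
        mad = np.median(np.abs(X - pre_center), axis=0) * 1.4826
        sd = X.std(axis=0)
        # floor the robust scale: a feature whose MAD is far below its SD
        # (heavy-tailed or near-discrete) would otherwise blow up ordinary
        # variation into huge pseudo-outliers
        pre_scale = np.maximum(mad, 0.3 * sd)
        pre_scale[pre_scale <= 1e-12] = 1.0
        X = (X - pre_center) / pre_scale
    if not 0.5 < alpha <= 1.0:
        raise ValueError("alpha must be in (0.5, 1]")
    if k < 1 or n <= k:
        raise ValueError("need more observations than retained components")
    m0 = X.mean(axis=0)
    Xc = X - m0
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = int(np.sum(S > 1e-9 * max(S[0], 1.0)))
    if r == 0:
        raise ValueError("degenerate data: all rows identical (zero variance)")
    if k > r:
        raise ValueError(f"cannot retain k={k} components from rank-{r} data")
    B = Vt[:r].T                      # (p, r)
    Z = Xc @ B
    rng = np.random.default_rng(seed)
    outl = _stahel_donoho_outlyingness(Z, rng, n_directions)
    h = int(np.ceil(alpha * n))
    keep = np.argsort(outl, kind="stable")[:h]
    mean_h = Z[keep].mean(axis=0)
    cov_h = np.cov(Z[keep], rowvar=False)
    cov_h = np.atleast_2d(cov_h)
    evals, evecs = np.linalg.eigh(cov_h)
    order = np.argsort(evals)[::-1]
    Vk = evecs[:, order[:k]]          # (r, k)
    scores = (Z - mean_h) @ Vk
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcd = MinCovDet(support_fraction=min(alpha, (n - 1) / n),
                        random_state=seed).fit(scores)
    loc, cov = mcd.location_, np.atleast_2d(mcd.covariance_)
    if np.linalg.det(cov) <= 0:
        cov = cov + 1e-12 * np.eye(k)
    # orthogonal distances within the reduced space
    resid = (Z - mean_h) - scores @ Vk.T
    od = np.linalg.norm(resid, axis=1)
    g = od ** (2.0 / 3.0)
    mu_g = float(np.median(g))
    sd_g = float(np.median(np.abs(g - mu_g)) * 1.4826)
    if sd_g <= 0:
        sd_g = float(g.std()) or 1e-9
    od_cutoff = max((mu_g + sd_g * stats.norm.ppf(0.975)) ** 1.5, 1e-9)
    model = AnomalyModel(
        k=k, alpha=alpha,
        center=m0 + (mean_h + Vk @ loc) @ B.T,
        loadings=B @ Vk,
        eigenvalues=np.sort(np.linalg.eigvalsh(cov))[::-1],
        sd_cutoff=float(np.sqrt(stats.chi2.ppf(0.975, df=k))),
        od_cutoff=float(od_cutoff),
        score_location=np.zeros(k),   # the MCD location is folded into `center`
        score_cov=cov,
        pre_center=pre_center,
        pre_scale=pre_scale,
    )
    return model


def categorize(sd: float, od: float, sd_cutoff: float, od_cutoff: float) -> str:
    """2x2 rule on (score distance, orthogonal distance)."""
    high_sd = sd > sd_cutoff
    high_od = od > od_cutoff
    if high_sd and high_od:
        return "bad_leverage"
    if high_sd:
        return "good_leverage"
    if high_od:
        return "orthogonal_outlier"
    return "regular"


def diagnose(features: FeatureVector | np.ndarray, model: AnomalyModel) -> PointDiagnosis:
    """Score/orthogonal distances and leverage category for one observation."""
    v = features.values if isinstance(features, FeatureVector) else np.asarray(features, float)
    if model.pre_scale is not None:
        v = (v - model.pre_center) / model.pre_scale
    d = v - model.center
    s = d @ model.loadings                        # (k,)
    cov_inv = np.linalg.inv(model.score_cov)
    sd = float(np.sqrt(s @ cov_inv @ s))
    od = float(np.linalg.norm(d - model.loadings @ s))
    return PointDiagnosis(sd, od, categorize(sd, od, model.sd_cutoff, model.od_cutoff))


# --------------------------------------------------------------- detectors

@dataclass
class DetectorModel:
    kind: str                   # 'tamper' or 'synthetic'
    estimator: object
    sensitivity: float
    specificity: float
    accuracy: float
    seed: int


def train_detector(features: np.ndarray, labels, kind: str, seed: int = 0) -> DetectorModel:
    """Fit the single-target detector for one abnormality type.

    ``tamper`` uses a random forest; ``synthetic`` a cubic-kernel SVM.
    Held-out sensitivity/specificity/accuracy come from an 80:20 split.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("detector training needs both classes")
    if kind == "tamper":
        est = RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    elif kind == "synthetic":
        est = make_pipeline(StandardScaler(),
                            SVC(kernel="poly", degree=3, C=1.0, random_state=seed))
    else:
        raise ValueError("kind must be 'tamper' or 'synthetic'")
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2, random_state=seed,
                                          stratify=y)
    est.fit(Xtr, ytr)
    pred = est.predict(Xte)
    tp = int(np.sum((pred == 1) & (yte == 1)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(yte)
    return DetectorModel(kind, est, sens, spec, acc, seed)


def classify_image(img: np.ndarray, anomaly_model: AnomalyModel,
                   tamper_model: DetectorModel, synthetic_model: DetectorModel,
                   localize: bool = False) -> ForensicsVerdict:
    """Run the synthetic / anomaly / tamper layers on one image.

    The three flags are independent single-target decisions; tamper
    localization runs only when the tamper flag is set and enabled.
    """
    fv = extract_features(img)
    diag = diagnose(fv, anomaly_model)
    x = fv.values.reshape(1, -1)
    tampered = bool(tamper_model.estimator.predict(x)[0])
    synthetic = bool(synthetic_model.estimator.predict(x)[0])
    verdict = ForensicsVerdict(synthetic=synthetic, anomalous=diag.anomalous,
                               tampered=tampered, diagnosis=diag)
    if tampered and localize:
        _, mask, box = localize_tamper(img)
        verdict.tamper_mask = mask
        verdict.tamper_box = box
    return verdict


# --------------------------------------------------------------- block noise

def _pca_noise_sigma(block: np.ndarray, patch: int = 7, stride: int = 2) -> float:
    """Noise SD from the smallest-eigenvalue tail of sliding-patch covariance."""
    h, w = block.shape
    if h < patch or w < patch:
        return float(block.std())
    ys = np.arange(0, h - patch + 1, stride)
    xs = np.arange(0, w - patch + 1, stride)
    patches = np.empty((len(ys) * len(xs), patch * patch))
    idx = 0
    for y in ys:
        for x in xs:
            patches[idx] = block[y:y + patch, x:x + patch].ravel()
            idx += 1
    if len(patches) < patch * patch:
        return float(block.std())
    cov = np.cov(patches, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(cov))
    tail = max(1, (patch * patch) // 2)
    return float(np.sqrt(max(np.median(evals[:tail]), 0.0)))


def estimate_block_noise(img: np.ndarray, block_size: int = 64) -> BlockNoiseMap:
    """Per-block PCA noise estimate on a ceil(H/bs) x ceil(W/bs) grid."""
    a = np.asarray(img, dtype=np.float64)
    if min(a.shape) < block_size:
        raise ValueError(f"image {a.shape} smaller than block size {block_size}")
    gh = -(-a.shape[0] // block_size)
    gw = -(-a.shape[1] // block_size)
    out = np.zeros((gh, gw))
    for by in range(gh):
        for bx in range(gw):
            blk = a[by * block_size:(by + 1) * block_size,
                    bx * block_size:(bx + 1) * block_size]
            out[by, bx] = _pca_noise_sigma(blk)
    return BlockNoiseMap(block_size, out)


# --------------------------------------------------------------- localization

def _ward_clusters(values: np.ndarray, k: int) -> np.ndarray:
    if k == 1 or len(values) < 2:
        return np.ones(len(values), dtype=int)
    link = linkage(values.reshape(-1, 1), method="ward")
    return fcluster(link, t=k, criterion="maxclust")


def _wss(values: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for c in np.unique(labels):
        v = values[labels == c]
        tot += float(np.sum((v - v.mean()) ** 2))
    return tot


def _gap_k(values: np.ndarray, max_clusters: int, n_ref: int, rng) -> int:
    """Cluster count 1..max_clusters maximising the gap statistic (uniform refs)."""
    ks = range(1, min(max_clusters, len(values)) + 1)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 1
    eps = 1e-12
    log_w = {k: np.log(_wss(values, _ward_clusters(values, k)) + eps) for k in ks}
    ref_log_w = {k: [] for k in ks}
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=len(values))
        for k in ks:
            ref_log_w[k].append(np.log(_wss(ref, _ward_clusters(ref, k)) + eps))
    gaps = {k: float(np.mean(ref_log_w[k]) - log_w[k]) for k in ks}
    return max(gaps, key=lambda k: (gaps[k], -k))


def _silhouette_k(values: np.ndarray, max_clusters: int) -> tuple[int, np.ndarray]:
    from sklearn.metrics import silhouette_score

    best_k, best_s, best_lab = 1, -np.inf, np.ones(len(values), dtype=int)
    for k in range(2, min(max_clusters, len(values) - 1) + 1):
        lab = _ward_clusters(values, k)
        if len(np.unique(lab)) < 2:
            continue
        s = silhouette_score(values.reshape(-1, 1), lab)
        if s > best_s:
            best_k, best_s, best_lab = k, s, lab
    return best_k, best_lab


def _block_pixel_counts(shape, block_size, grid_shape):
    hs = np.minimum(block_size, shape[0] - np.arange(grid_shape[0]) * block_size)
    ws = np.minimum(block_size, shape[1] - np.arange(grid_shape[1]) * block_size)
    return np.outer(hs, ws)


def localize_tamper(img: np.ndarray, coarse: int = 64, fine: int = 32,
                    max_clusters: int = 5, n_ref: int = 50, seed: int = 0):
    """Coarse-to-fine noise clustering; returns (class_map, tamper_mask, box).

    The coarse 64x64 noise grid is Ward-clustered with the cluster count
    chosen by the gap statistic (1 cluster => all pristine, empty mask).
    The fine 32x32 stage re-clusters blocks inside the coarse tampered
    region plus a one-coarse-block margin, with the count chosen by the
    silhouette index.  The class with the fewest pixels is tampered; a
    class covering more than half the image is never reported.
    ``box`` is half-open (x0, x1, y0, y1) or None.
    """
    a = np.asarray(img, dtype=np.float64)
    if min(a.shape) < coarse:
        raise ValueError(f"image must be at least {coarse}x{coarse}")
    rng = np.random.default_rng(seed)
    empty = (np.zeros(a.shape, dtype=int), np.zeros(a.shape, dtype=bool), None)

    cmap = estimate_block_noise(a, coarse)
    cvals = cmap.noise_level.ravel()
    k_c = _gap_k(cvals, max_clusters, n_ref, rng)
    if k_c == 1:
        return empty
    clab = _ward_clusters(cvals, k_c).reshape(cmap.noise_level.shape)
    cpix = _block_pixel_counts(a.shape, coarse, clab.shape)
    pix_per_class = {c: int(cpix[clab == c].sum()) for c in np.unique(clab)}
    tamper_class = min(pix_per_class, key=lambda c: (pix_per_class[c], c))
    if pix_per_class[tamper_class] > 0.5 * a.size:
        return empty

    # margin: dilate the coarse tampered blocks by one block
    import scipy.ndimage as ndi

    coarse_sel = ndi.binary_dilation(clab == tamper_class, iterations=1)

    fmap = estimate_block_noise(a, fine)
    fshape = fmap.noise_level.shape
    ratio = coarse // fine
    fine_sel = np.zeros(fshape, dtype=bool)
    for by, bx in np.argwhere(coarse_sel):
        fine_sel[by * ratio:(by + 1) * ratio, bx * ratio:(bx + 1) * ratio] = True
    fine_sel = fine_sel[: fshape[0], : fshape[1]]
    sel_idx = np.argwhere(fine_sel)
    fvals = fmap.noise_level[fine_sel]

    class_map = np.zeros(a.shape, dtype=int)
    fpix = _block_pixel_counts(a.shape, fine, fshape)
    if len(fvals) >= 4:
        _, flab = _silhouette_k(fvals, max_clusters)
    else:
        flab = np.ones(len(fvals), dtype=int)
    pix = {}
    for c in np.unique(flab):
        pix[c] = int(sum(fpix[tuple(b)] for b, l in zip(sel_idx, flab) if l == c))
    f_tamper = min(pix, key=lambda c: (pix[c], c))
    mask = np.zeros(a.shape, dtype=bool)
    for (by, bx), l in zip(sel_idx, flab):
        y0, x0 = by * fine, bx * fine
        class_map[y0:y0 + fine, x0:x0 + fine] = int(l)
        if l == f_tamper:
            mask[y0:y0 + fine, x0:x0 + fine] = True
    if len(np.unique(flab)) < 2:
        # fine stage could not separate; fall back to the coarse selection
        mask = np.zeros(a.shape, dtype=bool)
        for by, bx in np.argwhere(clab == tamper_class):
            mask[by * coarse:(by + 1) * coarse, bx * coarse:(bx + 1) * coarse] = True
    if mask.sum() > 0.5 * a.size or not mask.any():
        return empty
    ys, xs = np.nonzero(mask)
    box = (int(xs.min()), int(xs.max()) + 1, int(ys.min()), int(ys.max()) + 1)
    return class_map, mask, box


# --------------------------------------------------------------- reporting

def verdicts_to_frame(verdicts: dict[str, ForensicsVerdict]):
    """Per-image CSV-ready table of flags, distances and box coordinates."""
    import pandas as pd

    rows = []
    for name, v in verdicts.items():
        row = {"image": name, "synthetic": v.synthetic, "anomalous": v.anomalous,
               "tampered": v.tampered}
        if v.diagnosis is not None:
            row["score_distance"] = v.diagnosis.score_distance
            row["orthogonal_distance"] = v.diagnosis.orthogonal_distance
            row["category"] = v.diagnosis.category
        if v.tamper_box is not None:
            row.update(dict(zip(("box_x0", "box_x1", "box_y0", "box_y1"), v.tamper_box)))
        rows.append(row)
    return pd.DataFrame(rows)
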