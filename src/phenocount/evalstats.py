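"""Evaluation statistics: count error, detection metrics, method agreement,
count-model comparison and diagnostic-biomarker analysis.

Implemented from their primary formulations:

* per-unit percentage count error |y - x| / x * 100, pooled mean +/- SD;
* pooled cell-level sensitivity/specificity with greedy centroid matching;
* Passing-Bablok regression (shifted median of pairwise slopes, rank CIs,
  Kendall tau and a cusum linearity pre-test);
* Bland-Altman bias and 95% limits of agreement with their CIs;
* Gwet's AC1 chance-corrected agreement with its linearised variance;
* Poisson / NB / zero-inflated Poisson / zero-inflated NB count models
  with AIC selection and incidence-rate ratios;
* optimism-adjusted AUC by bootstrap, Youden cutoff, and 2x2 diagnostics
  with bootstrap CIs and leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "percentage_error", "detection_metrics", "passing_bablok", "bland_altman",
    "gwet_ac1", "fit_count_models", "roc_auc", "roc_optimism_auc",
    "youden_cutoff", "diagnostics_2x2",
    "PBFit", "BAResult", "AC1Result", "CountModelFit", "DiagnosticResult",
    "DetectionResult",
]


# --------------------------------------------------------------- count error

def percentage_error(x, y):
    """Per-unit |y - x| / x * 100 and the pooled mean +/- SD.

    Units with a zero reference count are excluded (logged via a warning).
    Returns ``(per_unit_errors, mean, sd)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired counts must have equal length")
    keep = x > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} unit(s) with zero reference count")
    err = np.abs(y[keep] - x[keep]) / x[keep] * 100.0
    if len(err) == 0:
        return err, float("nan"), float("nan")
    return err, float(err.mean()), float(err.std(ddof=1)) if len(err) > 1 else 0.0


# --------------------------------------------------------------- detection

@dataclass
class DetectionResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None


def _greedy_match(pred_xy, truth_xy, radii):
    """Greedy nearest-first matching; a pair matches when its distance is
    within the truth cell's radius.  Returns (matched_pred, matched_truth)."""
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return set(), set()
    d = np.linalg.norm(pred_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    used_p, used_t = set(), set()
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > radii[j]:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(int(i))
        used_t.add(int(j))
    return used_p, used_t


def _fov_confusion(preds, truths, phenotype, match_radius):
    """(tp, fp, tn, fn) for one phenotype on one FOV."""
    p_xy = np.array([[p["x"], p["y"]] for p in preds if p["phenotype"] == phenotype]
                    ).reshape(-1, 2)
    t_target = [t for t in truths if t["phenotype"] == phenotype]
    t_other = [t for t in truths if t["phenotype"] != phenotype]

    def radii(ts):
        return np.array([t.get("radius", match_radius) if match_radius is None
                         else match_radius for t in ts])

    t_xy = np.array([[t["x"], t["y"]] for t in t_target]).reshape(-1, 2)
    mp, mt = _greedy_match(p_xy, t_xy, radii(t_target))
    tp = len(mt)
    fn = len(t_target) - tp
    unmatched = np.array([p_xy[i] for i in range(len(p_xy)) if i not in mp]
                         ).reshape(-1, 2)
    o_xy = np.array([[t["x"], t["y"]] for t in t_other]).reshape(-1, 2)
    _, hit_other = _greedy_match(unmatched, o_xy, radii(t_other))
    fp = len(unmatched)
    tn = len(t_other) - len(hit_other)
    return tp, fp, tn, fn


def detection_metrics(per_fov, phenotypes=None, match_radius=None,
                      bootstrap: int = 1000, seed: int = 0) -> DetectionResult:
    """Pooled sensitivity/specificity across FOVs and phenotypes.

    ``per_fov`` is a list of ``(pred_cells, truth_cells)`` where each cell
    is a mapping with keys x, y, phenotype (truth cells may carry a
    matching ``radius``; otherwise ``match_radius`` is used).  TP/FN come
    from the truth side, FP from unmatched predictions, and TN from
    non-target-phenotype truth cells not claimed by a target prediction.
    CIs are percentile bootstrap over FOVs.
    """
    tables = []
    for preds, truths in per_fov:
        names = phenotypes
        if names is None:
            names = sorted({c["phenotype"] for c in list(preds) + list(truths)})
        tables.append(np.sum([_fov_confusion(preds, truths, ph, match_radius)
                              for ph in names], axis=0) if names else np.zeros(4))
    tables = np.asarray(tables, dtype=float)

    def _pooled(tab):
        tp, fp, tn, fn = tab
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return sens, spec

    tp, fp, tn, fn = tables.sum(axis=0)
    sens, spec = _pooled(tables.sum(axis=0))
    sens_ci = spec_ci = None
    if bootstrap and len(tables) > 1:
        rng = np.random.default_rng(seed)
        bs, bp = [], []
        for _ in range(bootstrap):
            idx = rng.integers(0, len(tables), len(tables))
            s, p = _pooled(tables[idx].sum(axis=0))
            bs.append(s)
            bp.append(p)
        sens_ci = tuple(np.nanpercentile(bs, [2.5, 97.5]))
        spec_ci = tuple(np.nanpercentile(bp, [2.5, 97.5]))
    return DetectionResult(int(tp), int(fp), int(tn), int(fn), sens, spec,
                           sens_ci, spec_ci)


# --------------------------------------------------------------- Passing-Bablok

@dataclass
class PBFit:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    kendall_tau: float
    kendall_p: float
    cusum_stat: float
    linearity_pass: bool
    n_slopes: int


def _pairwise_slopes(x, y):
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    s = np.empty(len(dx))
    nz = dx != 0
    s[nz] = dy[nz] / dx[nz]
    s[~nz] = np.sign(dy[~nz]) * np.inf
    return s[s != -1.0]   # the method excludes slopes equal to -1


def passing_bablok(x, y, conf: float = 0.95) -> PBFit:
    """Nonparametric method-comparison regression y = a + b x.

    Slope is the shifted median of pairwise slopes; CIs use the method's
    rank formulas.  Kendall's tau and a cusum linearity statistic
    (Kolmogorov-Smirnov bound 1.36 at 5%) are reported as pre-tests.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 10:
        raise ValueError("Passing-Bablok needs at least 10 pairs")
    s = np.sort(_pairwise_slopes(x, y))
    N = len(s)
    if N == 0:
        raise ValueError("no valid pairwise slopes (all pairs identical)")
    K = int(np.sum(s < -1.0))

    def _shifted_median(offset):
        if N % 2:
            return float(s[np.clip((N - 1) // 2 + offset, 0, N - 1)])
        lo = np.clip(N // 2 - 1 + offset, 0, N - 1)
        hi = np.clip(N // 2 + offset, 0, N - 1)
        return float((s[lo] + s[hi]) / 2.0)

    b = _shifted_median(K)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    C = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - C) / 2.0))
    M2 = N - M1 + 1
    b_lo = float(s[np.clip(M1 + K - 1, 0, N - 1)])
    b_hi = float(s[np.clip(M2 + K - 1, 0, N - 1)])
    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))

    tau, tau_p = stats.kendalltau(x, y)

    # cusum linearity: residual-sign random walk along the fitted line
    resid = y - (a + b * x)
    above = resid > 0
    below = resid < 0
    l, m = int(above.sum()), int(below.sum())
    if l == 0 or m == 0:
        cusum_stat, lin = 0.0, True
    else:
        score = np.zeros(n)
        score[above] = np.sqrt(m / l)
        score[below] = -np.sqrt(l / m)
        order = np.lexsort((y, x))
        cs = np.cumsum(score[order])
        cusum_stat = float(np.max(np.abs(cs)) / np.sqrt(l + m + 1))
        lin = cusum_stat < 1.36
    return PBFit(b, (b_lo, b_hi), a, (min(a_lo, a_hi), max(a_lo, a_hi)),
                 float(tau), float(tau_p), cusum_stat, bool(lin), N)


# --------------------------------------------------------------- Bland-Altman

@dataclass
class BAResult:
    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    sd: float


def bland_altman(x, y, conf: float = 0.95) -> BAResult:
    """Mean bias and 95% limits of agreement of y - x, with standard CIs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    t = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    lo, hi = bias - z * sd, bias + z * sd
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
    return BAResult(bias, (bias - t * se_bias, bias + t * se_bias), lo, hi,
                    (lo - t * se_loa, lo + t * se_loa),
                    (hi - t * se_loa, hi + t * se_loa), sd)


# --------------------------------------------------------------- Gwet's AC1

_LANDIS_KOCH = [(0.0, "slight"), (0.2, "fair"), (0.4, "moderate"),
                (0.6, "substantial"), (0.8, "almost perfect")]


@dataclass
class AC1Result:
    ac1: float
    ci: tuple[float, float]
    se: float
    pa: float
    pe: float
    benchmark: str


def gwet_ac1(rater_a, rater_b, conf: float = 0.95) -> AC1Result:
    """Gwet's first-order agreement coefficient for two raters.

    AC1 = (pa - pe) / (1 - pe) with chance agreement
    pe = sum_q pi_q (1 - pi_q) / (Q - 1); the variance uses Gwet's
    linearisation and the CI a Student-t quantile, truncated to [-1, 1].
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("raters must give one rating per unit")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 units")
    cats = np.unique(np.concatenate([a, b]))
    Q = len(cats)
    agree = (a == b).astype(float)
    pa = float(agree.mean())
    if Q == 1:
        return AC1Result(1.0, (1.0, 1.0), 0.0, pa, 0.0, "almost perfect")
    pi = np.array([(np.mean(a == q) + np.mean(b == q)) / 2.0 for q in cats])
    pe = float(np.sum(pi * (1 - pi)) / (Q - 1))
    ac1 = (pa - pe) / (1 - pe)
    # linearised per-unit components
    pe_i = np.array([
        np.sum(pi * (1 - pi) * 0) +
        np.sum([(float(a[i] == q) + float(b[i] == q)) / 2.0 * (1 - pi[qi])
                for qi, q in enumerate(cats)]) / (Q - 1)
        for i in range(n)
    ])
    g_star = (agree - pe) / (1 - pe)
    g_i = g_star - 2.0 * (1 - ac1) * (pe_i - pe) / (1 - pe)
    var = float(np.sum((g_i - ac1) ** 2) / (n * (n - 1)))
    se = np.sqrt(max(var, 0.0))
    t = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    ci = (max(-1.0, ac1 - t * se), min(1.0, ac1 + t * se))
    bench = "poor"
    for lo, name in _LANDIS_KOCH:
        if ac1 > lo:
            bench = name
    return AC1Result(float(ac1), ci, float(se), pa, pe, bench)


# --------------------------------------------------------------- count models

_FAMILY_ORDER = ("P", "NB", "ZIP", "ZINB")


@dataclass
class CountModelFit:
    family: str
    loglik: float
    aic: float
    n_params: int
    irr: float | None = None
    irr_ci: tuple[float, float] | None = None
    zero_or: float | None = None
    zero_or_ci: tuple[float, float] | None = None
    converged: bool = True
    message: str = ""


def _fit_one_family(family, y, exog):
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import (
        ZeroInflatedNegativeBinomialP, ZeroInflatedPoisson)
    from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

    kw = dict(disp=0, maxiter=500)
    if family == "P":
        res = Poisson(y, exog).fit(**kw)
    elif family == "NB":
        res = NegativeBinomial(y, exog).fit(**kw)
    elif family == "ZIP":
        res = ZeroInflatedPoisson(y, exog, exog_infl=exog, inflation="logit"
                                  ).fit(method="bfgs", **kw)
    elif family == "ZINB":
        res = ZeroInflatedNegativeBinomialP(y, exog, exog_infl=exog, p=2
                                            ).fit(method="bfgs", **kw)
    else:
        raise ValueError(family)
    return res


def fit_count_models(counts, group, families=_FAMILY_ORDER):
    """Fit P / NB / ZIP / ZINB with the enumeration method as a 2-level factor.

    Returns ``(fits, selected_family)``; selection is by lowest AIC with
    ties broken toward the simpler family.  The IRR is the exponentiated
    count-part group coefficient (Wald CI); zero-inflated families also
    report the zero-part odds ratio.
    """
    import statsmodels.api as sm

    y = np.asarray(counts, dtype=np.float64)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("group factor must have exactly 2 levels")
    ind = (g == levels[1]).astype(float)
    exog = sm.add_constant(ind)
    fits = []
    for family in families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _fit_one_family(family, y, exog)
            conv = bool(res.mle_retvals.get("converged", True)) if hasattr(
                res, "mle_retvals") else True
            names = list(res.model.exog_names)
            k_count = names.index("x1") if "x1" in names else 1
            params = np.asarray(res.params)
            ci = np.asarray(res.conf_int())
            if family in ("ZIP", "ZINB"):
                # parameter vector: [inflate_const, inflate_x1, const, x1, (alpha)]
                pnames = list(res.params.index) if hasattr(res.params, "index") else None
                if pnames:
                    i_cnt = pnames.index("x1")
                    i_zero = pnames.index("inflate_x1")
                else:
                    i_zero, i_cnt = 1, 3
                fit = CountModelFit(
                    family, float(res.llf), float(res.aic), int(res.df_model + 1),
                    irr=float(np.exp(params[i_cnt])),
                    irr_ci=tuple(np.exp(ci[i_cnt])),
                    zero_or=float(np.exp(params[i_zero])),
                    zero_or_ci=tuple(np.exp(ci[i_zero])),
                    converged=conv,
                )
            else:
                pnames = list(res.params.index) if hasattr(res.params, "index") else None
                i_cnt = pnames.index("x1") if pnames else 1
                fit = CountModelFit(
                    family, float(res.llf), float(res.aic), int(res.df_model + 1),
                    irr=float(np.exp(params[i_cnt])),
                    irr_ci=tuple(np.exp(ci[i_cnt])),
                    converged=conv,
                )
            if not (np.isfinite(fit.loglik) and np.isfinite(fit.aic)):
                fit.converged = False
                fit.message = "non-finite likelihood"
        except Exception as exc:  # noqa: BLE001 - optimisation can fail per family
            fit = CountModelFit(family, float("nan"), float("inf"), 0,
                                converged=False, message=str(exc))
            warnings.warn(f"{family} fit failed: {exc}")
        fits.append(fit)
    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no count-model family converged")
    best = min(usable, key=lambda f: (round(f.aic, 10), _FAMILY_ORDER.index(f.family)))
    return fits, best.family


# --------------------------------------------------------------- ROC / diagnostics

def roc_auc(scores, labels) -> float:
    """Apparent AUC in its Mann-Whitney form."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def roc_optimism_auc(scores, labels, B: int = 10_000, seed: int = 0):
    """Optimism-adjusted AUC via the bootstrap-refit procedure.

    Each bootstrap refits a binary logistic model, computes its AUC on the
    bootstrap sample and on the original sample; the mean difference is
    the optimism, subtracted from the apparent AUC.  Returns
    ``(apparent, optimism, adjusted)``.
    """
    from sklearn.linear_model import LogisticRegression

    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).astype(int)
    apparent = roc_auc(scores, labels)
    if B <= 0:
        return apparent, 0.0, apparent
    rng = np.random.default_rng(seed)
    n = len(scores)
    X = scores.reshape(-1, 1)
    opts = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        lr = LogisticRegression(C=1e6).fit(X[idx], yb)
        pb = lr.predict_proba(X[idx])[:, 1]
        po = lr.predict_proba(X)[:, 1]
        opts.append(roc_auc(pb, yb) - roc_auc(po, labels))
    optimism = float(np.mean(opts)) if opts else 0.0
    return apparent, optimism, apparent - optimism


def youden_cutoff(scores, labels):
    """Cutoff (predict positive when score >= cutoff) maximising J = sens + spec - 1.

    Ties break toward the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    cands = np.unique(scores)
    if len(cands) == 1:
        warnings.warn("single observed score value; returning it as the cutoff")
        return float(cands[0])
    best_c, best_j = None, -np.inf
    for c in cands:
        pred = scores >= c
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        if j > best_j:
            best_c, best_j = float(c), j
    return best_c


@dataclass
class DiagnosticResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    cutoff: float | None = None
    cis: dict = field(default_factory=dict)
    loocv: "DiagnosticResult | None" = None


def _metrics_from_counts(tp, fp, tn, fn):
    def _safe(n, d):
        return n / d if d else float("nan")

    return dict(
        sensitivity=_safe(tp, tp + fn), specificity=_safe(tn, tn + fp),
        ppv=_safe(tp, tp + fp), npv=_safe(tn, tn + fn),
        accuracy=_safe(tp + tn, tp + fp + tn + fn),
    )


def diagnostics_2x2(tp=None, fp=None, tn=None, fn=None, *, scores=None,
                    labels=None, cutoff=None, B: int = 1000,
                    loocv: bool = False, seed: int = 0) -> DiagnosticResult:
    """Sensitivity, specificity, PPV, NPV and accuracy of a 2x2 table.

    Either pass the four cells directly, or ``scores``/``labels`` (with an
    optional fixed ``cutoff``; otherwise the Youden cutoff is used).  With
    scores, CIs are percentile bootstrap over units (B iterations) and
    ``loocv=True`` adds a leave-one-out variant that re-selects the
    cutoff on every fold.
    """
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        labels = np.asarray(labels).astype(int)
        if cutoff is None:
            cutoff = youden_cutoff(scores, labels)
        pred = scores >= cutoff
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
    if None in (tp, fp, tn, fn):
        raise ValueError("all four cells must be defined")
    m = _metrics_from_counts(tp, fp, tn, fn)
    res = DiagnosticResult(tp, fp, tn, fn, cutoff=cutoff, **m)
    if scores is not None and B > 0:
        rng = np.random.default_rng(seed)
        n = len(scores)
        samples = {k: [] for k in m}
        for _ in range(B):
            idx = rng.integers(0, n, n)
            yb, sb = labels[idx], scores[idx]
            pred = sb >= cutoff
            mb = _metrics_from_counts(
                int(np.sum(pred & (yb == 1))), int(np.sum(pred & (yb == 0))),
                int(np.sum(~pred & (yb == 0))), int(np.sum(~pred & (yb == 1))))
            for k, v in mb.items():
                samples[k].append(v)
        res.cis = {k: tuple(np.nanpercentile(v, [2.5, 97.5]))
                   for k, v in samples.items()}
    if loocv:
        if scores is None:
            raise ValueError("LOOCV needs scores and labels")
        cells = np.zeros(4, dtype=int)  # tp fp tn fn
        for i in range(len(scores)):
            rest = np.ones(len(scores), dtype=bool)
            rest[i] = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c_i = youden_cutoff(scores[rest], labels[rest])
            pos = scores[i] >= c_i
            if labels[i] == 1:
                cells[0 if pos else 3] += 1
            else:
                cells[1 if pos else 2] += 1
        res.loocv = DiagnosticResult(*map(int, cells),
                                     **_metrics_from_counts(*cells))
    return res


# --------------------------------------------------------------- plots

def plot_passing_bablok(x, y, fit: PBFit, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.scatter(x, y, s=12)
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, xs, "k--", label="identity")
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
            label=f"fit: y = {fit.intercept:.2f} + {fit.slope:.2f} x")
    ax.legend()
    return ax


def plot_bland_altman(x, y, res: BAResult, ax=None):
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ax = ax or plt.gca()
    ax.scatter((x + y) / 2, y - x, s=12)
    for v, style in ((res.bias, "--"), (res.loa_lower, "-"), (res.loa_upper, "-")):
        ax.axhline(v, linestyle=style, color="C1")
    return ax


def plot_roc(scores, labels, ax=None):
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    ax = ax or plt.gca()
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return ax
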