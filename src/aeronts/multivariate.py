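"""Multivariate overview and supervised contrasts of the chemistry matrix.

PCA is computed with NIPALS (the workhorse for wide MS matrices), and
class contrasts with OPLS-DA: one predictive component plus orthogonal
components whose scores carry no class covariance. Per-variable influence
is summarized as VIP (mean square 1) and pCorr (correlation of the scaled
variable with the predictive score vector); markers are variables with
VIP > 1.5 and |pCorr| > 0.5.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import SampleRecord

MARITIME_REGIONS = (1, 2)
CONTINENTAL_REGIONS = (3, 4, 5, 6)


def dichotomize(samples: list[SampleRecord], rule: str,
                temperature_split_C: float = 15.0) -> np.ndarray:
    """Binary class vector (+1 / -1) for the temperature or maritime rule.

    temperature: +1 (high) iff mean temperature > 15 degC (ties -> low,
    with a warning). maritime: +1 iff maritime regions (1, 2) outweigh the
    four continental regions combined.
    """
    y = []
    for s in samples:
        if rule == "temperature":
            if s.mean_temp_C == temperature_split_C:
                warnings.warn(
                    f"sample {s.sample_id}: mean temperature exactly at the "
                    f"{temperature_split_C} degC split; assigned to the low class")
            y.append(1.0 if s.mean_temp_C > temperature_split_C else -1.0)
        elif rule == "maritime":
            mar = sum(s.cluster_weights.get(r, 0.0) for r in MARITIME_REGIONS)
            con = sum(s.cluster_weights.get(r, 0.0) for r in CONTINENTAL_REGIONS)
            y.append(1.0 if mar > con else -1.0)
        else:
            raise ValueError(f"unknown dichotomization rule {rule!r}")
    return np.array(y)


def _scale(X: np.ndarray, scaling: str,
           center: np.ndarray | None = None,
           sd: np.ndarray | None = None):
    if center is None:
        center = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    Xc = X - center
    if scaling == "none":
        pass
    elif scaling == "uv":
        Xc = Xc / sd
    elif scaling == "pareto":
        Xc = Xc / np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return Xc, center, sd


# ----------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    scores: np.ndarray      # (n, k)
    loadings: np.ndarray    # (p, k)
    explained: np.ndarray   # (k,) fraction of total variance


def nipals_pca(X: np.ndarray, n_components: int = 2, scaling: str = "none",
               tol: float = 1e-10, max_iter: int = 1000) -> PcaResult:
    """NIPALS principal components of the (centered, optionally scaled) matrix."""
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc, _, _ = _scale(X, scaling)
    if not np.any(Xc):
        raise ValueError("constant matrix: PCA undefined")
    total_ss = float((Xc ** 2).sum())
    scores, loadings, explained = [], [], []
    E = Xc.copy()
    for _ in range(n_components):
        col = int(np.argmax((E ** 2).sum(axis=0)))
        t = E[:, col].copy()
        if not np.any(t):
            break
        for _ in range(max_iter):
            p = E.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = E @ p
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        scores.append(t)
        loadings.append(p)
        explained.append(float(t @ t) / total_ss)
        E = E - np.outer(t, p)
    return PcaResult(scores=np.column_stack(scores),
                     loadings=np.column_stack(loadings),
                     explained=np.array(explained))


# --------------------------------------------------------------- OPLS-DA

@dataclass
class OplsModel:
    t_pred: np.ndarray          # (n,) predictive scores
    p_pred: np.ndarray          # (p,) predictive loadings
    w_pred: np.ndarray          # (p,) predictive weights (unit norm)
    q: float                    # y-loading
    t_ortho: np.ndarray         # (n, k)
    p_ortho: np.ndarray         # (p, k)
    w_ortho: np.ndarray         # (p, k)
    r2: float
    q2: float
    vip: np.ndarray             # (p,)
    pcorr: np.ndarray           # (p,)
    scaling: str = "pareto"
    center: np.ndarray = field(default=None, repr=False)
    sd: np.ndarray = field(default=None, repr=False)


def _opls_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """One predictive + n_ortho orthogonal components (Trygg & Wold)."""
    E = Xc.copy()
    w = E.T @ yc
    w /= np.linalg.norm(w)
    t_os, p_os, w_os = [], [], []
    for _ in range(n_ortho):
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        t_os.append(t_o)
        p_os.append(p_o)
        w_os.append(w_o)
    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    stack = (lambda v: np.column_stack(v) if v else np.zeros((Xc.shape[0], 0)))
    return w, t, p, q, stack(t_os), \
        (np.column_stack(p_os) if p_os else np.zeros((Xc.shape[1], 0))), \
        (np.column_stack(w_os) if w_os else np.zeros((Xc.shape[1], 0)))


def _predict_scores(Xc: np.ndarray, w, w_ortho, p_ortho) -> np.ndarray:
    E = Xc.copy()
    for k in range(w_ortho.shape[1]):
        t_o = E @ w_ortho[:, k]
        E = E - np.outer(t_o, p_ortho[:, k])
    return E @ w


def oplsda(X: np.ndarray, y: np.ndarray, n_ortho: int = 1, cv_folds: int = 7,
           seed: int = 0, scaling: str = "pareto") -> OplsModel:
    """Fit OPLS-DA on a samples x variables matrix against a binary class.

    R2 is the explained class variance, Q2 its k-fold cross-validated
    counterpart; VIP derives from the predictive weights (mean square 1)
    and pCorr is the Pearson correlation of each scaled variable with the
    predictive score vector.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    for c in classes:
        if (y == c).sum() < cv_folds:
            raise ValueError(
                f"class {c} has fewer members than cv_folds={cv_folds}")
    Xc, center, sd = _scale(X, scaling)
    yc = y - y.mean()
    w, t, p, q, t_os, p_os, w_os = _opls_core(Xc, yc, n_ortho)
    yhat = t * q
    ssy = float(yc @ yc)
    r2 = 1 - float(((yc - yhat) ** 2).sum()) / ssy
    # cross-validated Q2
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv_folds)
    press = 0.0
    for fold in folds:
        mask = np.ones(len(y), bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        if np.unique(ytr).size < 2:
            continue
        Xtr_s, c_tr, sd_tr = _scale(Xtr, scaling)
        ytr_c = ytr - ytr.mean()
        wf, tf, pf, qf, _, pof, wof = _opls_core(Xtr_s, ytr_c, n_ortho)
        Xte_s, _, _ = _scale(X[fold], scaling, center=c_tr, sd=sd_tr)
        t_te = _predict_scores(Xte_s, wf, wof, pof)
        yhat_te = t_te * qf + ytr.mean()
        press += float(((y[fold] - yhat_te) ** 2).sum())
    q2 = 1 - press / ssy
    # VIP over the single predictive component: sqrt(p) * |w_j|
    vip = np.sqrt(Xc.shape[1]) * np.abs(w)
    # pCorr: correlation of each scaled variable with t_pred
    t_sd = t.std()
    x_sd = Xc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcorr = (Xc.T @ (t - t.mean())) / (len(t) * x_sd * t_sd)
    pcorr = np.nan_to_num(np.clip(pcorr, -1, 1))
    return OplsModel(t_pred=t, p_pred=p, w_pred=w, q=q, t_ortho=t_os,
                     p_ortho=p_os, w_ortho=w_os, r2=r2, q2=q2, vip=vip,
                     pcorr=pcorr, scaling=scaling, center=center, sd=sd)


def select_markers(model: OplsModel, vip_min: float = 1.5,
                   pcorr_min: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Indices of class markers: VIP strictly above ``vip_min`` and |pCorr|
    strictly above ``pcorr_min``, split by the sign of pCorr."""
    sel = (model.vip > vip_min) & (np.abs(model.pcorr) > pcorr_min)
    pos = np.flatnonzero(sel & (model.pcorr > 0))
    neg = np.flatnonzero(sel & (model.pcorr < 0))
    return pos, neg


@dataclass
class ContrastSummary:
    mean_dbe_a: float | None
    mean_dbe_b: float | None
    p_value: float | None
    dbe_values_a: list[float] = field(default_factory=list)
    dbe_values_b: list[float] = field(default_factory=list)
    class_counts_a: dict[str, int] = field(default_factory=dict)
    class_counts_b: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def contrast_descriptors(dbe_a: list[float], dbe_b: list[float],
                         classes_a: list[str] | None = None,
                         classes_b: list[str] | None = None) -> ContrastSummary:
    """Per-class DBE means, heteroatom-class counts and a Welch's t-test
    for the DBE difference between two marker sets."""
    def _counts(cls):
        out: dict[str, int] = {}
        for c in cls or []:
            out[c] = out.get(c, 0) + 1
        return out

    summary = ContrastSummary(
        mean_dbe_a=float(np.mean(dbe_a)) if dbe_a else None,
        mean_dbe_b=float(np.mean(dbe_b)) if dbe_b else None,
        p_value=None,
        dbe_values_a=list(dbe_a), dbe_values_b=list(dbe_b),
        class_counts_a=_counts(classes_a), class_counts_b=_counts(classes_b))
    if not dbe_a or not dbe_b:
        summary.notes.append("a marker class has no assigned formulas; "
                             "descriptors omitted for it")
        return summary
    if len(dbe_a) > 1 and len(dbe_b) > 1:
        if np.ptp(dbe_a) == 0 and np.ptp(dbe_b) == 0 and dbe_a[0] == dbe_b[0]:
            summary.p_value = 1.0
        else:
            summary.p_value = float(stats.ttest_ind(dbe_a, dbe_b, equal_var=False).pvalue)
    return summary
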