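"""Two-class discriminant analysis of copy-number profiles.

Fisher linear discriminant between herbivores and carnivores on gene-family
copy numbers: coefficients ``w`` proportional to ``S_pooled^-1 (m1 - m2)``,
DF scores ``w^T (x - grand centroid)`` oriented so herbivores score high,
Wilks'-lambda stepwise forward feature selection, leave-one-out and
clade-holdout validation, and a phylogenetic variant that whitens the data
by a lambda-scaled Brownian covariance before discriminating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .trees import PhyloTree, is_ultrametric, lambda_transform, vcv_matrix

__all__ = [
    "DiscriminantModel",
    "StepwiseTrace",
    "fit_lda",
    "df_scores",
    "predict",
    "wilks_lambda",
    "stepwise_wilks",
    "loocv",
    "clade_holdout",
    "fit_pfda",
    "optimal_pfda_lambda",
]

HERBIVORE, CARNIVORE = "herbivore", "carnivore"


@dataclass
class DiscriminantModel:
    features: list[str]
    classes: tuple[str, str]  # (positive/high-score class, other)
    means: dict[str, np.ndarray] = field(repr=False)
    pooled_cov: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    priors: dict[str, float]
    grand_centroid: np.ndarray = field(repr=False)
    threshold: float  # score cut in DF-score space (decide class0 if >=)
    ridge: float = 0.0

    def to_json(self) -> str:
        return json.dumps({
            "format": "dietcnv-discriminant-v1",
            "features": self.features,
            "classes": list(self.classes),
            "means": {k: v.tolist() for k, v in self.means.items()},
            "pooled_cov": self.pooled_cov.tolist(),
            "w": self.w.tolist(),
            "priors": self.priors,
            "grand_centroid": self.grand_centroid.tolist(),
            "threshold": self.threshold,
            "ridge": self.ridge,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        doc = json.loads(text)
        if doc.get("format") != "dietcnv-discriminant-v1":
            raise ValueError("unrecognized model document")
        return cls(
            features=doc["features"],
            classes=tuple(doc["classes"]),
            means={k: np.asarray(v) for k, v in doc["means"].items()},
            pooled_cov=np.asarray(doc["pooled_cov"]),
            w=np.asarray(doc["w"]),
            priors=doc["priors"],
            grand_centroid=np.asarray(doc["grand_centroid"]),
            threshold=doc["threshold"],
            ridge=doc["ridge"],
        )


def _check_X(X: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        vals = X.to_numpy(dtype=float)
        feats = list(X.columns)
    else:
        vals = np.asarray(X, dtype=float)
        feats = [f"f{i}" for i in range(vals.shape[1])]
    lab = np.asarray(labels)
    if len(lab) != vals.shape[0]:
        raise ValueError("labels must match rows of X")
    return vals, lab, feats


def _scatter(vals: np.ndarray, lab: np.ndarray, classes) -> tuple[np.ndarray, np.ndarray, dict]:
    means = {c: vals[lab == c].mean(axis=0) for c in classes}
    W = np.zeros((vals.shape[1],) * 2)
    for c in classes:
        d = vals[lab == c] - means[c]
        W += d.T @ d
    grand = vals.mean(axis=0)
    B = np.zeros_like(W)
    for c in classes:
        nc = (lab == c).sum()
        d = (means[c] - grand)[:, None]
        B += nc * (d @ d.T)
    return W, B, means


def fit_lda(
    X: pd.DataFrame,
    labels,
    priors: dict[str, float] | None = None,
    ridge: float | None = None,
) -> DiscriminantModel:
    """Fisher LDA for two classes; ``w`` solves the pooled-covariance
    closed form ``S^-1 (m_h - m_c)``.

    ``priors`` default to training class proportions. A singular pooled
    covariance (constant feature columns happen with count data) gets a
    small ridge ``1e-8 * trace / p`` unless one is supplied.
    """
    vals, lab, feats = _check_X(X, labels)
    classes = sorted(set(lab))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    n_by = {c: int((lab == c).sum()) for c in classes}
    if min(n_by.values()) < 2:
        raise ValueError("each class needs >= 2 members")
    # orient scores: herbivore high if present, else first class high
    if HERBIVORE in classes:
        pos = HERBIVORE
    else:
        pos = classes[0]
    neg = classes[0] if classes[1] == pos else classes[1]
    n = len(lab)
    if priors is None:
        priors = {c: n_by[c] / n for c in classes}
    else:
        tot = sum(priors.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("priors must sum to 1")
        priors = dict(priors)
    W, _, means = _scatter(vals, lab, classes)
    S = W / (n - 2)  # pooled within-class covariance
    p = S.shape[0]
    used_ridge = 0.0
    try:
        w = linalg.solve(S, means[pos] - means[neg], assume_a="pos")
    except linalg.LinAlgError:
        used_ridge = ridge if ridge is not None else 1e-8 * np.trace(S) / p
        if used_ridge <= 0:
            raise ValueError("singular pooled covariance; supply a ridge")
        w = linalg.solve(S + used_ridge * np.eye(p),
                         means[pos] - means[neg], assume_a="pos")
    grand = vals.mean(axis=0)
    # decision boundary for equal-covariance Gaussians with priors:
    # classify pos iff w^T x - w^T (m_pos + m_neg)/2 + log(pi_pos/pi_neg) > 0
    mid = float(w @ ((means[pos] + means[neg]) / 2 - grand))
    threshold = mid - np.log(priors[pos] / priors[neg])
    return DiscriminantModel(
        features=feats, classes=(pos, neg),
        means=means, pooled_cov=S, w=w, priors=priors,
        grand_centroid=grand, threshold=threshold, ridge=used_ridge,
    )


def df_scores(model: DiscriminantModel, X: pd.DataFrame) -> pd.Series:
    """Discriminant-function score per species: ``w^T (x - centroid)``."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.features if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        vals = X[model.features].to_numpy(dtype=float)
        index = X.index
    else:
        vals = np.asarray(X, dtype=float)
        index = pd.RangeIndex(len(vals))
    return pd.Series(
        (vals - model.grand_centroid) @ model.w, index=index, name="df_score"
    )


def predict(model: DiscriminantModel, X: pd.DataFrame) -> pd.Series:
    scores = df_scores(model, X)
    pos, neg = model.classes
    return scores.map(lambda s: pos if s > model.threshold else neg
                      ).rename("predicted")


def wilks_lambda(X: pd.DataFrame, labels, subset=None) -> float:
    """Wilks' lambda det(W) / det(W + B) on a feature subset."""
    vals, lab, feats = _check_X(X, labels)
    if subset is not None:
        idx = [feats.index(f) for f in subset]
        if not idx:
            raise ValueError("subset is empty")
        vals = vals[:, idx]
    classes = sorted(set(lab))
    W, B, _ = _scatter(vals, lab, classes)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise linalg.LinAlgError("singular within-class scatter")
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class StepwiseTrace:
    selected: list[str]
    wilks: list[float]
    p_enter: list[float]
    alpha_enter: float


def stepwise_wilks(
    X: pd.DataFrame, labels, alpha_enter: float = 0.2
) -> StepwiseTrace:
    """Greedy forward selection minimising Wilks' lambda.

    At each step the candidate giving the smallest overall lambda enters
    if its partial-F p-value is <= ``alpha_enter``; selection stops when
    no candidate qualifies.
    """
    vals, lab, feats = _check_X(X, labels)
    n = len(lab)
    g = len(set(lab))
    selected: list[str] = []
    lams: list[float] = []
    ps: list[float] = []
    lam_old = 1.0
    remaining = list(feats)
    while remaining:
        best = None
        for f in remaining:
            try:
                lam = wilks_lambda(X, labels, selected + [f])
            except linalg.LinAlgError:
                continue
            if best is None or lam < best[1]:
                best = (f, lam)
        if best is None:
            break
        f, lam_new = best
        k = len(selected)
        df2 = n - g - k
        if df2 <= 0 or lam_new <= 0:
            break
        F = (lam_old / lam_new - 1.0) * df2 / (g - 1)
        p = float(stats.f.sf(F, g - 1, df2))
        if p > alpha_enter or lam_new >= lam_old:
            break
        selected.append(f)
        lams.append(lam_new)
        ps.append(p)
        lam_old = lam_new
        remaining.remove(f)
    return StepwiseTrace(selected, lams, ps, alpha_enter)


def loocv(
    X: pd.DataFrame, labels, priors: dict[str, float] | None = None
) -> tuple[float, pd.Series]:
    """Leave-one-out cross-validation by naive refitting.

    Priors are held at the full-data values (or the supplied fixed
    priors) in every fold, matching the fixed-prior usage of the
    phylogenetic variant.
    """
    vals, lab, feats = _check_X(X, labels)
    classes = sorted(set(lab))
    n_by = {c: (lab == c).sum() for c in classes}
    if min(n_by.values()) < 3:
        raise ValueError("each class needs >= 3 members for LOOCV")
    if priors is None:
        priors = {c: n_by[c] / len(lab) for c in classes}
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(lab))
    preds = []
    for i in range(len(lab)):
        mask = np.ones(len(lab), dtype=bool)
        mask[i] = False
        Xi = pd.DataFrame(vals[mask], columns=feats)
        model = fit_lda(Xi, lab[mask], priors=priors)
        pred = predict(model, pd.DataFrame(vals[[i]], columns=feats)).iloc[0]
        preds.append(pred)
    preds = pd.Series(preds, index=index, name="predicted")
    accuracy = float((preds.to_numpy() == lab).mean())
    return accuracy, preds


def clade_holdout(
    X: pd.DataFrame, labels, clade, priors: dict[str, float] | None = None
) -> pd.Series:
    """Fit without one clade; predict the held-out clade's members."""
    clade = [s for s in clade]
    index = X.index
    unknown = set(clade) - set(index)
    if unknown:
        raise ValueError(f"clade members not in data: {sorted(unknown)}")
    if not clade:
        return pd.Series(dtype=object, name="predicted")
    train_mask = ~index.isin(clade)
    lab = pd.Series(np.asarray(labels), index=index)
    train_lab = lab[train_mask]
    if train_lab.nunique() < 2:
        raise ValueError("training set must retain both classes")
    model = fit_lda(X.loc[train_mask], train_lab.to_numpy(), priors=priors)
    return predict(model, X.loc[clade])


def _whiten(X: pd.DataFrame, tree: PhyloTree, lam: float):
    cov = vcv_matrix(tree).reorder(list(X.index))
    scaled = lambda_transform(cov, lam)
    L = linalg.cholesky(scaled.C, lower=True)
    Xw = linalg.solve_triangular(L, X.to_numpy(dtype=float), lower=True)
    ones_w = linalg.solve_triangular(L, np.ones(len(X.index)), lower=True)
    # project out the whitened intercept (phylogenetic GLS centring)
    proj = ones_w @ Xw / (ones_w @ ones_w)
    Xc = Xw - np.outer(ones_w, proj)
    return pd.DataFrame(Xc, index=X.index, columns=X.columns)


def fit_pfda(
    X: pd.DataFrame,
    labels,
    tree: PhyloTree,
    lam: float,
    priors: dict[str, float],
) -> tuple[DiscriminantModel, pd.DataFrame]:
    """Phylogenetic discriminant analysis: whiten, then discriminate.

    Rows of X (and the intercept) are whitened by the inverse Cholesky
    factor of the lambda-scaled Brownian covariance of the (ultrametric)
    tree; an ordinary LDA with the supplied *fixed* priors is fitted to
    the whitened data. At lambda = 0 on a unit-depth tree the whitening
    is the identity and the result coincides with plain LDA.

    Returns the fitted model together with the whitened feature table
    (needed to score/predict in the whitened space).
    """
    if not is_ultrametric(tree, rel_tol=1e-6):
        raise ValueError("tree must be ultrametric; use make_ultrametric")
    missing = set(X.index) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    Xc = _whiten(X, tree, lam)
    model = fit_lda(Xc, labels, priors=priors)
    return model, Xc


def optimal_pfda_lambda(
    X: pd.DataFrame,
    labels,
    tree: PhyloTree,
    grid=None,
    priors: dict[str, float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search lambda minimising training misclassification.

    Default grid 0 to 0.1 in steps of 0.01; ties break to the smallest
    lambda. Returns (lambda*, per-lambda table).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 0.1 + 1e-9, 0.01), 10)
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    lab = np.asarray(labels)
    if priors is None:
        classes = sorted(set(lab))
        priors = {c: float((lab == c).mean()) for c in classes}
    rows = []
    for lam in grid:
        model, Xc = fit_pfda(X, lab, tree, lam, priors)
        pred = predict(model, Xc)
        rows.append({"lambda": float(lam),
                     "misclassification": float((pred.to_numpy() != lab).mean())})
    table = pd.DataFrame(rows)
    best = table.loc[table["misclassification"].idxmin()]
    # idxmin takes the first minimum; grid is ascending, so ties -> smallest
    return float(best["lambda"]), table
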