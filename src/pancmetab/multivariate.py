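"""OPLS-DA: orthogonal projections to latent structures, discriminant variant.

The model separates the variation in X that is predictive of a binary class
from structured variation orthogonal to it.  Orthogonal components are
removed sequentially by the orthogonal-filtering construction, then a single
predictive PLS component is fitted on the filtered matrix.  Model quality is
summarized by R2Y (explained class variance on the training data) and Q2
(class variance predicted in stratified k-fold cross-validation; 7 folds by
default, the convention of the commercial software this emulates).  R2Y
above 0.7 together with Q2 above 0.5 is conventionally read as a good
discriminant model.

With ``n_ortho=0`` the model reduces exactly to single-component PLS1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALINGS = ("uv", "pareto", "center")


@dataclass
class OplsModel:
    n_ortho: int
    scaling: str
    class_encoding: dict
    feature_names: list[str]
    # column scaling parameters (over kept columns)
    x_mean: np.ndarray
    x_scale: np.ndarray
    kept: np.ndarray  # boolean mask over original columns
    y_mean: float
    # orthogonal components
    w_ortho: np.ndarray  # n_ortho x p
    p_ortho: np.ndarray  # n_ortho x p
    t_ortho: np.ndarray  # n x n_ortho (training scores)
    # predictive component
    weights: np.ndarray  # p
    loadings: np.ndarray  # p
    scores: np.ndarray  # n (training)
    q: float  # y-loading
    r2y: float
    q2: float | None = None

    @property
    def predictive_loadings(self) -> pd.Series:
        return pd.Series(self.loadings, index=self.feature_names)


def _scale_columns(X: np.ndarray, scaling: str):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        scale = sd
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    elif scaling == "center":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
    return mean, scale, sd


def _encode_y(y, positive_class=None) -> tuple[np.ndarray, dict]:
    y = np.asarray(y)
    classes = list(dict.fromkeys(y.tolist()))  # order of appearance
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_class is not None:
        if positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not in labels")
        classes = [c for c in classes if c != positive_class] + [positive_class]
    encoding = {classes[0]: 0.0, classes[1]: 1.0}
    return np.array([encoding[v] for v in y]), encoding


def fit_opls_da(
    X,
    y,
    n_ortho: int = 1,
    scaling: str = "uv",
    positive_class=None,
) -> OplsModel:
    """Fit an OPLS-DA model with ``n_ortho`` orthogonal components.

    X may be an array or DataFrame (samples x variables); y holds two class
    labels with at least 3 samples each.  Zero-variance columns (after
    centering) are dropped with a warning.  The predictive weight vector is
    oriented so that its score correlates positively with the class encoded
    as 1, hence a positive predictive loading means "higher in that class".
    """
    feature_names = (
        list(X.columns) if isinstance(X, pd.DataFrame)
        else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, dtype=float)
    y_enc, encoding = _encode_y(y, positive_class)
    counts = [int((y_enc == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 3:
        raise ValueError(f"need >= 3 samples per class, got counts {counts}")

    mean, scale, sd = _scale_columns(X, scaling)
    kept = sd > 0
    if not kept.all():
        dropped = [feature_names[j] for j in np.flatnonzero(~kept)]
        warnings.warn(f"dropping zero-variance variables: {dropped}")
    if not kept.any():
        raise ValueError("all variables have zero variance")
    Xs = (X[:, kept] - mean[kept]) / np.where(scale[kept] == 0, 1, scale[kept])
    rank = np.linalg.matrix_rank(Xs)
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} must be < rank(X)={rank}")

    y_mean = float(y_enc.mean())
    yc = y_enc - y_mean

    E = Xs.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = E.T @ yc
        w = w / np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = E.T @ yc
    w = w / np.linalg.norm(w)
    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    if q < 0:  # orient scores with the class encoded 1
        w, t, p, q = -w, -t, -p, -q
    yhat = t * q
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss_tot

    p_full = len(feature_names)
    def expand(v):
        out = np.zeros(p_full)
        out[np.flatnonzero(kept)] = v
        return out

    return OplsModel(
        n_ortho=len(W_o),
        scaling=scaling,
        class_encoding=encoding,
        feature_names=feature_names,
        x_mean=mean,
        x_scale=np.where(scale == 0, 1, scale),
        kept=kept,
        y_mean=y_mean,
        w_ortho=np.array([expand(v) for v in W_o]).reshape(len(W_o), p_full),
        p_ortho=np.array([expand(v) for v in P_o]).reshape(len(P_o), p_full),
        t_ortho=np.array(T_o).T if T_o else np.zeros((X.shape[0], 0)),
        weights=expand(w),
        loadings=expand(p),
        scores=t,
        q=q,
        r2y=r2y,
    )


def predict(model: OplsModel, X) -> np.ndarray:
    """Continuous class prediction for new samples (training scale)."""
    X = np.asarray(X, dtype=float)
    Xs = (X[:, model.kept] - model.x_mean[model.kept]) / model.x_scale[model.kept]
    k = model.kept
    for w_o, p_o in zip(model.w_ortho, model.p_ortho):
        t_o = Xs @ w_o[k]
        Xs = Xs - np.outer(t_o, p_o[k])
    t = Xs @ model.weights[k]
    return t * model.q + model.y_mean


def stratified_folds(y_enc: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment (round-robin within each class)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y_enc), dtype=int)
    for v in np.unique(y_enc):
        idx = np.flatnonzero(y_enc == v)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def cross_validate_q2(
    X,
    y,
    n_ortho: int = 1,
    folds: int = 7,
    scaling: str = "uv",
    seed: int = 0,
    positive_class=None,
) -> float:
    """Stratified k-fold cross-validated Q2 = 1 - PRESS/SS_tot.

    Held-out class values are predicted by models refitted without them;
    folds are stratified by class and seeded, so the value is deterministic
    given the seed.  If a split leaves a class absent from training the
    folds are re-stratified with a shifted seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y_enc, _ = _encode_y(y, positive_class)
    folds = min(folds, len(y_enc))

    press = 0.0
    for attempt in range(10):
        parts = stratified_folds(y_enc, folds, seed + attempt)
        ok = all(
            len(np.unique(y_enc[np.setdiff1d(np.arange(len(y_enc)), test)])) == 2
            for test in parts if len(test)
        )
        if ok:
            break
    else:
        raise ValueError("could not stratify folds with both classes in training")

    press = 0.0
    for test in parts:
        if not len(test):
            continue
        train = np.setdiff1d(np.arange(len(y_enc)), test)
        # refit on the globally encoded 0/1 labels so folds share the encoding
        model = fit_opls_da(
            X[train], y_enc[train], n_ortho=n_ortho, scaling=scaling,
            positive_class=1.0,
        )
        yhat = predict(model, X[test])
        press += float(((y_enc[test] - yhat) ** 2).sum())
    ss_tot = float(((y_enc - y_enc.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def opls_summary(model: OplsModel) -> pd.DataFrame:
    """Variables ranked by |predictive loading|; positive loading means
    higher in the class encoded as 1."""
    df = pd.DataFrame({
        "variable": model.feature_names,
        "predictive_loading": model.loadings,
        "predictive_weight": model.weights,
    })
    df["abs_loading"] = df["predictive_loading"].abs()
    df = df.sort_values("abs_loading", ascending=False).drop(columns="abs_loading")
    return df.reset_index(drop=True)
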