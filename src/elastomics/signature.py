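"""Sparse PLS discriminant gene signatures.

Learns a low-dimensional latent-variable model that separates "stiff" from
"soft" biopsies from their (log-transformed, standardized) expression
profiles, with per-component gene selection: each component keeps exactly
``keep_x`` genes by soft-thresholding the X loading vector inside the
NIPALS iteration, as in sparse PLS-DA.  External samples are classified by
projecting them with the training centering/scaling constants and
assigning the nearest class centroid in latent space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class SignatureModel:
    """Fitted (sparse) PLS-DA model.

    ``loadings`` (genes x components) are the unit-norm X weight vectors;
    ``x_loadings_p`` are the deflation loadings used when projecting new
    data.  ``centroids`` maps class label -> mean latent score vector of
    the training samples of that class.
    """

    gene_ids: list[str]
    classes: list[str]
    n_components: int
    keep_x: list[int]
    x_mean: np.ndarray
    x_std: np.ndarray
    loadings: np.ndarray  # genes x comps (w)
    x_loadings_p: np.ndarray  # genes x comps (p)
    centroids: dict[str, np.ndarray]
    train_scores: np.ndarray | None = None
    train_labels: list[str] | None = None

    @property
    def selected_genes(self) -> list[list[str]]:
        """Genes with nonzero loading, per component."""
        out = []
        for c in range(self.n_components):
            nz = np.nonzero(self.loadings[:, c])[0]
            out.append([self.gene_ids[i] for i in nz])
        return out

    @property
    def signature_genes(self) -> list[str]:
        """Union of selected genes over components, in gene order."""
        mask = (self.loadings != 0).any(axis=1)
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def to_json(self) -> str:
        payload = {
            "gene_ids": self.gene_ids,
            "classes": self.classes,
            "n_components": self.n_components,
            "keep_x": self.keep_x,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "loadings": self.loadings.tolist(),
            "x_loadings_p": self.x_loadings_p.tolist(),
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(
            gene_ids=d["gene_ids"],
            classes=d["classes"],
            n_components=d["n_components"],
            keep_x=d["keep_x"],
            x_mean=np.asarray(d["x_mean"]),
            x_std=np.asarray(d["x_std"]),
            loadings=np.asarray(d["loadings"]),
            x_loadings_p=np.asarray(d["x_loadings_p"]),
            centroids={k: np.asarray(v) for k, v in d["centroids"].items()},
        )


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries stay nonzero."""
    if keep >= len(w):
        return w.copy()
    absw = np.abs(w)
    # threshold = (keep+1)-th largest magnitude
    thr = np.partition(absw, len(w) - keep - 1)[len(w) - keep - 1]
    out = np.sign(w) * np.maximum(absw - thr, 0.0)
    return out


def _dummy_matrix(y: Sequence[str], classes: list[str]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for i, lab in enumerate(y):
        Y[i, classes.index(lab)] = 1.0
    return Y - Y.mean(axis=0, keepdims=True)


def fit_splsda(
    X: pd.DataFrame,
    y: Sequence[str],
    n_components: int = 1,
    keep_x: int | Sequence[int] | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SignatureModel:
    """Sparse PLS-DA by NIPALS with per-component soft-thresholding.

    ``X`` is samples x genes (e.g. log-normalized counts), ``y`` binary
    class labels.  Genes are standardized to zero mean and unit variance
    using training data only; constant genes are dropped with a warning.
    ``keep_x`` is the number of genes retained per component (int or one
    value per component; None keeps all genes = plain PLS-DA).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [str(c) for c in X.columns]
    y = [str(v) for v in y]
    if len(y) != len(X):
        raise ValueError("y must have one label per row of X")
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("binary classification only")
    n, G0 = X.shape
    if n_components > min(n - 1, G0):
        raise ValueError("n_components exceeds the rank bound")

    std = X.std(axis=0, ddof=1).to_numpy()
    keep_mask = std > 0
    if not keep_mask.all():
        warnings.warn(f"dropping {(~keep_mask).sum()} constant gene columns")
    genes = [g for g, m in zip(X.columns, keep_mask) if m]
    Xv = X.loc[:, genes].to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=1)
    Xc = (Xv - mean) / sd
    G = len(genes)

    if keep_x is None:
        keeps = [G] * n_components
    elif isinstance(keep_x, (int, np.integer)):
        keeps = [int(keep_x)] * n_components
    else:
        keeps = [int(k) for k in keep_x]
        if len(keeps) != n_components:
            raise ValueError("one keep_x per component required")
    if any(k < 1 or k > G for k in keeps):
        raise ValueError(f"keep_x must lie in [1, {G}]")

    Y = _dummy_matrix(y, classes)
    Xd = Xc.copy()
    Yd = Y.copy()
    W = np.zeros((G, n_components))
    P = np.zeros((G, n_components))
    T = np.zeros((n, n_components))
    for c in range(n_components):
        u = Yd[:, 0].copy()
        if np.allclose(u, 0):
            u = Yd[:, 1].copy()
        w = np.zeros(G)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            w_new = _soft_threshold_keep(w_new, keeps[c])
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError("degenerate component: zero loading vector")
            w_new /= norm
            t = Xd @ w_new
            cvec = Yd.T @ t / (t @ t)
            u_new = Yd @ cvec / (cvec @ cvec)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        cvec = Yd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, cvec)
        W[:, c], P[:, c], T[:, c] = w, p, t

    centroids = {
        lab: T[np.array(y) == lab].mean(axis=0) for lab in classes
    }
    return SignatureModel(
        gene_ids=list(genes),
        classes=classes,
        n_components=n_components,
        keep_x=keeps,
        x_mean=mean,
        x_std=sd,
        loadings=W,
        x_loadings_p=P,
        centroids=centroids,
        train_scores=T,
        train_labels=list(y),
    )


def fit_plsda(X: pd.DataFrame, y: Sequence[str], n_components: int = 1) -> SignatureModel:
    """Plain PLS-DA: sparse fit with all genes retained per component."""
    return fit_splsda(X, y, n_components=n_components, keep_x=None)


def transform(model: SignatureModel, X_new: pd.DataFrame) -> np.ndarray:
    """Latent scores of new samples under the training projection."""
    missing = [g for g in model.gene_ids if g not in X_new.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} model genes missing from new data: {missing[:10]}"
        )
    Xv = X_new.loc[:, model.gene_ids].to_numpy(dtype=float)
    Xc = (Xv - model.x_mean) / model.x_std
    T = np.zeros((len(Xc), model.n_components))
    Xd = Xc
    for c in range(model.n_components):
        t = Xd @ model.loadings[:, c]
        Xd = Xd - np.outer(t, model.x_loadings_p[:, c])
        T[:, c] = t
    return T


def predict_class(model: SignatureModel, X_new: pd.DataFrame) -> pd.DataFrame:
    """Classify new samples by nearest centroid in latent space.

    Requires every model gene to be present (no silent imputation); returns
    the predicted class plus latent scores per sample.
    """
    T = transform(model, X_new)
    cents = np.stack([model.centroids[c] for c in model.classes])
    d2 = ((T[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    pred = [model.classes[i] for i in np.argmin(d2, axis=1)]
    out = pd.DataFrame(
        {"predicted_class": pred}, index=X_new.index
    )
    for c in range(model.n_components):
        out[f"score_{c + 1}"] = T[:, c]
    return out


def _balanced_error(y_true: Sequence[str], y_pred: Sequence[str], classes: list[str]) -> float:
    errs = []
    yt = np.array(y_true)
    yp = np.array(y_pred)
    for lab in classes:
        mask = yt == lab
        if mask.any():
            errs.append(float((yp[mask] != lab).mean()))
    return float(np.mean(errs))


def cross_validated_ber(
    X: pd.DataFrame,
    y: Sequence[str],
    n_components: int,
    keep_x: int | None,
    folds: int,
    repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balanced error rate per repeat of stratified k-fold CV."""
    y = np.array([str(v) for v in y])
    classes = sorted(set(y))
    out = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        preds = np.empty(len(y), dtype=object)
        for tr, te in skf.split(X, y):
            model = fit_splsda(X.iloc[tr], y[tr], n_components=n_components, keep_x=keep_x)
            preds[te] = predict_class(model, X.iloc[te])["predicted_class"].to_numpy()
        out[r] = _balanced_error(y, preds, classes)
    return out


def tune_splsda(
    X: pd.DataFrame,
    y: Sequence[str],
    keep_x_grid: Sequence[int],
    n_components_grid: Sequence[int] = (1, 2),
    folds: int = 5,
    repeats: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """Choose (n_components, keep_x) by repeated stratified k-fold CV.

    Selects the smallest model (fewest components, then fewest genes per
    component) whose mean balanced error rate is within one standard error
    of the best configuration — a parsimony-first rule.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = [str(v) for v in y]
    counts = pd.Series(y).value_counts()
    if folds > counts.min():
        raise ValueError("folds exceeds the smallest class count")
    if not keep_x_grid or not n_components_grid:
        raise ValueError("grids must be nonempty")

    records = []
    for nc in n_components_grid:
        for kx in keep_x_grid:
            bers = cross_validated_ber(X, y, nc, int(kx), folds, repeats, rng)
            records.append(
                {
                    "n_components": int(nc),
                    "keep_x": int(kx),
                    "mean_ber": float(bers.mean()),
                    "se_ber": float(bers.std(ddof=1) / np.sqrt(len(bers)))
                    if len(bers) > 1
                    else 0.0,
                }
            )
    grid = pd.DataFrame(records)
    best = grid.loc[grid["mean_ber"].idxmin()]
    thresh = best["mean_ber"] + best["se_ber"]
    ok = grid[grid["mean_ber"] <= thresh]
    chosen = ok.sort_values(["n_components", "keep_x"]).iloc[0]
    return {
        "n_components": int(chosen["n_components"]),
        "keep_x": int(chosen["keep_x"]),
        "mean_ber": float(chosen["mean_ber"]),
        "grid": grid,
    }
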