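"""Multivariate chemometrics: preprocessing, PCA, clustering and OPLS-DA.

OPLS-DA separates class-predictive from class-orthogonal variation: each
orthogonal round removes from X the systematic variation uncorrelated with
the class response before predictive PLS components are extracted.  Model
quality is summarised by R2X(cum) and R2Y(cum) (in-model fractions of X and
Y variance), Q2(cum) (cross-validated predictive fraction of Y variance),
per-feature VIP scores (squared values average 1 by construction), and a
label-permutation test whose negative Q2 intercept supports model validity.

Matrices follow the samples x features orientation throughout.  Columns are
autoscaled (mean-centred, unit variance) by default before PCA/OPLS-DA, the
conventional default for this model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import FeatureTable, get_logger

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "OplsModel",
    "PermutationResult",
    "preprocess",
    "pca",
    "top_variable_clustering",
    "opls_da",
    "vip",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class ScaledMatrix:
    """samples x features matrix with its transform/scaling provenance."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    transform: str = "none"    # none | log2p1
    scaling: str = "none"      # none | center | unit-variance
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def subset(self, samples: list[str]) -> "ScaledMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return ScaledMatrix(
            self.values[idx], [self.sample_ids[i] for i in idx],
            list(self.feature_ids), self.transform, self.scaling,
            self.centers, self.scales,
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def preprocess(
    table: FeatureTable | pd.DataFrame,
    transform: str = "log2p1",
    scaling: str = "unit-variance",
) -> ScaledMatrix:
    """Transform and column-scale a feature table for multivariate modelling.

    ``log2p1`` applies log2(abundance + 1) elementwise before scaling.
    Unit-variance scaling of a feature column across samples is the same
    operation as the per-feature (row-wise, in heatmap orientation) Z-score
    used for visualisation.  Zero-variance features cannot be autoscaled and
    are dropped with a warning.
    """
    if isinstance(table, FeatureTable):
        df = table.abundance
    else:
        df = table
    X = df.to_numpy(dtype=float).T  # samples x features
    sample_ids = list(df.columns)
    feature_ids = list(df.index)
    if transform == "log2p1":
        if (X < 0).any():
            raise ValueError("log2p1 requires nonnegative abundances")
        X = np.log2(X + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    centers = scales = None
    if scaling in ("center", "unit-variance"):
        centers = X.mean(axis=0)
        X = X - centers
        if scaling == "unit-variance":
            scales = X.std(axis=0, ddof=1)
            keep = scales > 0
            if not keep.all():
                get_logger().warning(
                    "%d zero-variance features dropped before autoscaling",
                    int((~keep).sum()),
                )
                X = X[:, keep]
                centers = centers[keep]
                scales = scales[keep]
                feature_ids = [f for f, k in zip(feature_ids, keep) if k]
            X = X / scales
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    return ScaledMatrix(X, sample_ids, feature_ids, transform, scaling, centers, scales)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray      # samples x components
    loadings: np.ndarray    # features x components
    r2x_per_component: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]


def pca(matrix: ScaledMatrix, n_components: int = 2) -> PcaModel:
    """Principal component analysis by SVD of the (centred) scaled matrix.

    r2x per component is the component variance over the total variance of
    the matrix handed in.
    """
    X = matrix.values - matrix.values.mean(axis=0)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)={min(n-1, p)}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    total = (s**2).sum()
    r2x = s[:n_components] ** 2 / total
    return PcaModel(scores, loadings, r2x, list(matrix.sample_ids), list(matrix.feature_ids))


# ---------------------------------------------------------------------------
# Hierarchical clustering of top-variable features
# ---------------------------------------------------------------------------


def top_variable_clustering(
    table: FeatureTable,
    k: int = 100,
    method: str = "average",
    metric: str = "euclidean",
) -> dict:
    """Cluster the k most-variable features and the samples.

    Features are ranked by the variance of their log2(abundance+1) values
    (ties broken by feature_id for determinism); the selected block is
    per-feature Z-scored, and both axes are clustered agglomeratively.
    Returns linkage matrices and dendrogram leaf orders for both axes plus
    the selected feature ids.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > table.n_features:
        raise ValueError(f"k={k} exceeds the {table.n_features} available features")
    logged = np.log2(table.abundance.to_numpy(dtype=float) + 1.0)
    variances = pd.Series(logged.var(axis=1, ddof=1), index=table.feature_ids)
    # mergesort is stable; pre-sorting the index makes tie order deterministic
    order = variances.loc[sorted(variances.index)].sort_values(
        ascending=False, kind="mergesort"
    )
    top = list(order.index[:k])
    block = pd.DataFrame(logged, index=table.feature_ids,
                         columns=table.abundance.columns).loc[top]
    z = block.sub(block.mean(axis=1), axis=0)
    sd = block.std(axis=1, ddof=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    feat_link = hierarchy.linkage(pdist(z.to_numpy(), metric=metric), method=method)
    samp_link = hierarchy.linkage(pdist(z.to_numpy().T, metric=metric), method=method)
    return {
        "features": top,
        "feature_linkage": feat_link,
        "sample_linkage": samp_link,
        "feature_order": [top[i] for i in hierarchy.leaves_list(feat_link)],
        "sample_order": [z.columns[i] for i in hierarchy.leaves_list(samp_link)],
        "zscores": z,
    }


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _dummy_code(y: np.ndarray | list) -> tuple[np.ndarray, list]:
    """Centred response matrix: one +/-1 column for 2 classes, indicators otherwise."""
    labels = np.asarray(y)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("at least 2 classes are required")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if len(classes) == 2:
        Y = np.where(labels == classes[1], 1.0, -1.0)[:, None]
    else:
        Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    return Y - Y.mean(axis=0), classes


def _joint_weights(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Unit-norm X-weight vector maximally covarying with (multi-column) Y."""
    C = X.T @ Y  # features x q
    if C.shape[1] == 1:
        w = C[:, 0]
    else:
        # dominant left singular vector of X'Y via the small q x q eigenproblem
        M = C.T @ C
        vals, vecs = np.linalg.eigh(M)
        w = C @ vecs[:, -1]
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("X carries no covariance with y (degenerate fit)")
    return w / nrm


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (predictive + orthogonal structure)."""

    classes: list
    weights: np.ndarray        # features x A, predictive w
    loadings: np.ndarray       # features x A, predictive p
    scores: np.ndarray         # samples x A, predictive t
    y_loadings: np.ndarray     # q x A, c
    ortho_weights: np.ndarray  # features x n_ortho
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray   # samples x n_ortho
    ssy_per_component: np.ndarray
    r2x_cum: float
    r2y_cum: float
    q2_cum: float | None
    n_orthogonal: int
    feature_ids: list[str] = field(default_factory=list)

    @property
    def vip(self) -> np.ndarray:
        return vip(self)


def _fit_core(
    X: np.ndarray, Y: np.ndarray, n_orthogonal: int, n_predictive: int
) -> dict:
    """One OPLS fit on centred X, Y; no cross-validation."""
    Xc = X.copy()
    Yc = Y.copy()
    ss_x = (X**2).sum()
    ss_y = (Y**2).sum()

    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        w = _joint_weights(Xc, Yc)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12 * max(1.0, np.linalg.norm(p)):
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    W, P, T, Cc, ssy = [], [], [], [], []
    for _ in range(n_predictive):
        if (Yc**2).sum() <= 1e-14 * max(ss_y, 1.0):
            break
        w = _joint_weights(Xc, Yc)
        t = Xc @ w
        tt = t @ t
        if tt <= 0:
            break
        c = Yc.T @ t / tt
        p = Xc.T @ t / tt
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, c)
        W.append(w)
        P.append(p)
        T.append(t)
        Cc.append(c)
        ssy.append(tt * (c @ c))

    stack = lambda v, shape: (np.stack(v, axis=1) if v else np.zeros(shape))
    nfeat, nsamp, q = X.shape[1], X.shape[0], Y.shape[1]
    return {
        "W": stack(W, (nfeat, 0)),
        "P": stack(P, (nfeat, 0)),
        "T": stack(T, (nsamp, 0)),
        "C": stack(Cc, (q, 0)),
        "W_o": stack(W_o, (nfeat, 0)),
        "P_o": stack(P_o, (nfeat, 0)),
        "T_o": stack(T_o, (nsamp, 0)),
        "ssy": np.array(ssy),
        "r2y": 1.0 - (Yc**2).sum() / ss_y,
        "r2x": 1.0 - (Xc**2).sum() / ss_x,
    }


def _predict(fit: dict, X_new: np.ndarray) -> np.ndarray:
    """Predict centred responses for new (identically scaled) samples."""
    Xc = X_new.copy()
    for a in range(fit["W_o"].shape[1]):
        t_o = Xc @ fit["W_o"][:, a]
        Xc = Xc - np.outer(t_o, fit["P_o"][:, a])
    Y_hat = np.zeros((X_new.shape[0], fit["C"].shape[0]))
    for a in range(fit["W"].shape[1]):
        t = Xc @ fit["W"][:, a]
        Xc = Xc - np.outer(t, fit["P"][:, a])
        Y_hat += np.outer(t, fit["C"][:, a])
    return Y_hat


def _cross_validated_q2(
    X: np.ndarray, Y: np.ndarray, n_orthogonal: int, n_predictive: int,
    n_folds: int = 7,
) -> float:
    """Q2(cum) by round-robin k-fold cross-validation (PRESS over SS)."""
    n = X.shape[0]
    folds = np.arange(n) % min(n_folds, n)
    press = 0.0
    ss = 0.0
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        xm = X[train].mean(axis=0)
        ym = Y[train].mean(axis=0)
        try:
            fit = _fit_core(X[train] - xm, Y[train] - ym, n_orthogonal, n_predictive)
            y_hat = _predict(fit, X[test] - xm) + ym
        except ValueError:
            y_hat = np.broadcast_to(ym, Y[test].shape)
        press += ((Y[test] - y_hat) ** 2).sum()
        ss += ((Y[test] - ym) ** 2).sum()
    return 1.0 - press / ss


def opls_da(
    X: ScaledMatrix | np.ndarray,
    y: list | np.ndarray,
    n_orthogonal: int | str = 1,
    compute_q2: bool = True,
    cv_folds: int = 7,
) -> OplsModel:
    """Fit an OPLS-DA model of class labels on a scaled matrix.

    Orthogonal variation is removed iteratively before the predictive
    component(s): one predictive component for a two-class model, one per
    independent response column (n_classes - 1) for the global multi-class
    model.  ``n_orthogonal='auto'`` adds orthogonal components while Q2
    improves by more than 0.01.
    """
    if isinstance(X, ScaledMatrix):
        Xv = X.values
        feature_ids = list(X.feature_ids)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_ids = [f"x{j}" for j in range(Xv.shape[1])]
    Y, classes = _dummy_code(y)
    Xv = Xv - Xv.mean(axis=0)
    n_predictive = 1 if len(classes) == 2 else len(classes) - 1

    if n_orthogonal == "auto":
        best_n, best_q2 = 0, -np.inf
        for n_o in range(0, min(Xv.shape[0] - 2, 5) + 1):
            q2 = _cross_validated_q2(Xv, Y, n_o, n_predictive, cv_folds)
            if q2 > best_q2 + 0.01:
                best_n, best_q2 = n_o, q2
            elif n_o > best_n:
                break
        n_orthogonal = best_n
    n_orthogonal = int(n_orthogonal)

    fit = _fit_core(Xv, Y, n_orthogonal, n_predictive)
    q2 = (
        _cross_validated_q2(Xv, Y, n_orthogonal, n_predictive, cv_folds)
        if compute_q2
        else None
    )
    return OplsModel(
        classes=classes,
        weights=fit["W"],
        loadings=fit["P"],
        scores=fit["T"],
        y_loadings=fit["C"],
        ortho_weights=fit["W_o"],
        ortho_loadings=fit["P_o"],
        ortho_scores=fit["T_o"],
        ssy_per_component=fit["ssy"],
        r2x_cum=float(fit["r2x"]),
        r2y_cum=float(fit["r2y"]),
        q2_cum=None if q2 is None else float(q2),
        n_orthogonal=fit["T_o"].shape[1],
        feature_ids=feature_ids,
    )


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ); because each
    weight vector has unit norm, mean(VIP^2) = 1 on any fitted model.
    """
    W = model.weights
    if W.shape[1] == 0:
        raise ValueError("model has no predictive components (unfit)")
    ssy = model.ssy_per_component
    p = W.shape[0]
    num = (W**2 * ssy[None, :]).sum(axis=1)
    return np.sqrt(p * num / ssy.sum())


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    r2y: np.ndarray            # permuted R2Y values
    q2: np.ndarray             # permuted Q2 values
    correlation: np.ndarray    # |label correlation| per permutation
    original_r2y: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float
    n_permutations: int


def permutation_test(
    X: ScaledMatrix | np.ndarray,
    y: list | np.ndarray,
    n_permutations: int = 200,
    seed: int | None = None,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
) -> PermutationResult:
    """Label-permutation validity test of an OPLS-DA model.

    The class vector is permuted uniformly ``n_permutations`` times and the
    model refit with identical structure; R2Y/Q2 are recorded against the
    absolute correlation between permuted and original (dummy-coded)
    labels.  Intercepts come from least-squares lines through all permuted
    points plus the unpermuted model at correlation 1.
    """
    if seed is None:
        raise ValueError("an explicit seed is required (reproducibility)")
    if n_permutations < 20:
        get_logger().warning(
            "n_permutations=%d < 20: intercept estimates will be unstable",
            n_permutations,
        )
    rng = np.random.default_rng(seed)
    labels = np.asarray(y)
    Y0, _ = _dummy_code(labels)
    y0_flat = Y0.ravel()

    ref = opls_da(X, labels, n_orthogonal=n_orthogonal, cv_folds=cv_folds)
    r2s, q2s, cors = [], [], []
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        yp = labels[perm]
        Yp = Y0[perm]
        denom = np.linalg.norm(Yp.ravel()) * np.linalg.norm(y0_flat)
        cor = abs(float(Yp.ravel() @ y0_flat) / denom) if denom > 0 else 0.0
        try:
            m = opls_da(X, yp, n_orthogonal=n_orthogonal, cv_folds=cv_folds)
            r2s.append(m.r2y_cum)
            q2s.append(m.q2_cum)
        except ValueError:  # degenerate permutation
            r2s.append(0.0)
            q2s.append(0.0)
        cors.append(cor)
    r2s, q2s, cors = np.array(r2s), np.array(q2s), np.array(cors)
    xs = np.concatenate([cors, [1.0]])
    r_line = np.polyfit(xs, np.concatenate([r2s, [ref.r2y_cum]]), 1)
    q_line = np.polyfit(xs, np.concatenate([q2s, [ref.q2_cum]]), 1)
    return PermutationResult(
        r2y=r2s,
        q2=q2s,
        correlation=cors,
        original_r2y=float(ref.r2y_cum),
        original_q2=float(ref.q2_cum),
        r2_intercept=float(r_line[1]),
        q2_intercept=float(q_line[1]),
        n_permutations=n_permutations,
    )
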