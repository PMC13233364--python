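"""Integration of untargeted signatures with the targeted FFA axis.

Three couplings: Spearman rank correlation (BH-FDR controlled within the
analysis family) between signature scores and FFA-derived metrics;
chemical-superclass enrichment of discriminant tiers against the
discriminant background (two-sided Fisher exact, BH-FDR within tier); and a
repeated stratified threefold multinomial elastic-net classification of the
four regimes from the FFA matrix, scored strictly out-of-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .chemometrics import ScaledMatrix
from .io import FeatureTable, SampleDesign

__all__ = [
    "SignatureScore",
    "ClassifierReport",
    "signature_score",
    "spearman_couple",
    "spearman_permutation_p",
    "bh_fdr",
    "superclass_enrichment",
    "elasticnet_classify",
]

#: FFA-derived metric family used for signature coupling.
FFA_METRIC_FAMILY = (
    "total", "SFA_pct", "MUFA_pct", "PUFA_pct", "oleic_pct", "linoleic_pct", "OL_ratio",
)


@dataclass
class SignatureScore:
    """Per-sample score of a feature signature (mean member Z-score)."""

    signature: str
    scores: pd.Series  # index sample_id


def signature_score(matrix: ScaledMatrix, members: set[str] | list[str],
                    name: str = "signature") -> SignatureScore:
    """Mean per-feature Z-scored log2(abundance+1) over the member set.

    The matrix should be autoscaled (unit-variance columns); an empty or
    absent member set is an error, never a zero score.
    """
    members = list(members)
    if not members:
        raise ValueError("signature member set is empty")
    missing = [m for m in members if m not in matrix.feature_ids]
    if missing:
        raise ValueError(f"signature members absent from matrix: {missing[:5]}")
    idx = [matrix.feature_ids.index(m) for m in members]
    scores = matrix.values[:, idx].mean(axis=1)
    return SignatureScore(name, pd.Series(scores, index=matrix.sample_ids))


def spearman_permutation_p(
    x: np.ndarray, y: np.ndarray, n_resamples: int = 100_000, seed: int = 0
) -> float:
    """Two-sided Monte-Carlo permutation p for Spearman's rho.

    Ranks (average for ties) are fixed for x; y-ranks are permuted
    ``n_resamples`` times and the vectorised rank correlation compared with
    the observed |rho|.  Add-one correction keeps p in (0, 1].
    """
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum()) * np.sqrt((ryc**2).sum())
    if denom == 0:
        raise ValueError("constant vector: rho undefined")
    obs = abs(float(rxc @ ryc) / denom)
    # permute y-ranks via argsort of uniforms, correlations in one matmul
    perm_idx = np.argsort(rng.random((n_resamples, n)), axis=1)
    perm_corr = np.abs((ryc[perm_idx] @ rxc) / denom)
    exceed = int((perm_corr >= obs - 1e-12).sum())
    return (1 + exceed) / (1 + n_resamples)


def spearman_couple(
    scores: list[SignatureScore],
    metrics: pd.DataFrame,
    metric_names: tuple[str, ...] = FFA_METRIC_FAMILY,
    n_resamples: int = 100_000,
    seed: int = 0,
    small_n: int = 12,
) -> pd.DataFrame:
    """Spearman coupling of every signature x FFA-metric pair with BH-FDR.

    rho uses exact average ranks; for n <= ``small_n`` the two-sided p is a
    seeded Monte-Carlo permutation p (the t approximation is unreliable at
    these sample sizes), otherwise the analytic approximation.  q values are
    BH-FDR within the whole signature x metric family.
    """
    rows = []
    for sig in scores:
        for met in metric_names:
            if met not in metrics.columns:
                continue
            joined = pd.concat([sig.scores, metrics[met]], axis=1, join="inner").dropna()
            if len(joined) < 4:
                raise ValueError(f"fewer than 4 paired samples for {sig.signature} x {met}")
            x = joined.iloc[:, 0].to_numpy(float)
            y = joined.iloc[:, 1].to_numpy(float)
            if np.allclose(x, x[0]) or np.allclose(y, y[0]):
                rows.append({"signature": sig.signature, "metric": met,
                             "rho": np.nan, "p": np.nan, "flag": "constant"})
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            if len(x) <= small_n:
                p = spearman_permutation_p(x, y, n_resamples=n_resamples, seed=seed)
            else:
                p = float(stats.spearmanr(x, y).pvalue)
            rows.append({"signature": sig.signature, "metric": met,
                         "rho": rho, "p": p, "flag": ""})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q values: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def superclass_enrichment(
    tiers: dict[str, set[str]],
    annotations: FeatureTable | pd.DataFrame,
    background: set[str],
) -> pd.DataFrame:
    """Superclass over-/under-representation of each tier vs the background.

    Background is the discriminant union; every tier must be a subset.  For
    each tier x superclass, the 2x2 table (in-tier & in-class, in-tier &
    not, out-of-tier & in-class, out-of-tier & not) is tested two-sided by
    Fisher's exact test; odds ratios use a Haldane 0.5 correction when any
    cell is zero; q values are BH-FDR within each tier.
    """
    if isinstance(annotations, FeatureTable):
        ann = annotations.annotation["superclass"]
    else:
        ann = annotations["superclass"]
    ann = ann.reindex(sorted(background)).fillna("nan")
    rows = []
    for tier_name, members in tiers.items():
        extra = members - background
        if extra:
            raise ValueError(f"tier {tier_name!r} not a subset of background: {sorted(extra)[:5]}")
        in_tier = ann.index.isin(members)
        for sclass in sorted(ann.unique()):
            in_class = (ann == sclass).to_numpy()
            a = int((in_tier & in_class).sum())
            b = int((in_tier & ~in_class).sum())
            c = int((~in_tier & in_class).sum())
            d = int((~in_tier & ~in_class).sum())
            if min(a, b, c, d) == 0:
                odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
                flag = "haldane"
            else:
                odds = a * d / (b * c)
                flag = ""
            rows.append(
                {
                    "tier": tier_name, "superclass": sclass,
                    "in_tier_in_class": a, "in_tier_not": b,
                    "not_tier_in_class": c, "not_tier_not": d,
                    "odds_ratio": odds, "p": _fisher_two_sided(a, b, c, d),
                    "flag": flag,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for tier_name in tiers:
        mask = out["tier"] == tier_name
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


@dataclass
class ClassifierReport:
    """Out-of-fold performance of the multinomial elastic-net classifier."""

    classes: list[str]
    confusion_counts: pd.DataFrame
    confusion_percent: pd.DataFrame  # row-normalised
    accuracy: float
    macro_f1: float
    macro_auc: float
    coefficient_ranking: pd.Series   # mean |coefficient| per feature, descending
    fold_assignments: pd.DataFrame   # repeat x sample fold bookkeeping


def elasticnet_classify(
    ffa: pd.DataFrame,
    design: SampleDesign,
    alpha_mix: float = 0.5,
    n_repeats: int = 20,
    seed: int = 0,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
) -> ClassifierReport:
    """Regime classification from the FFA matrix, scored out-of-fold.

    Repeated stratified threefold cross-validation; within each training
    fold, features are standardised on the training data only and the
    penalty strength is chosen by an inner stratified split before refitting
    on the full training fold.  Pooled out-of-fold probabilities over all
    repeats feed Accuracy, Macro-F1, one-vs-rest Macro-AUC and the
    row-normalised confusion matrix; features are ranked by mean absolute
    coefficient across classes, folds and repeats.
    """
    X = ffa.T.loc[list(design.sample_ids)].to_numpy(dtype=float)  # samples x species
    y = np.array(design.regimes)
    classes = sorted(set(y.tolist()))
    counts = pd.Series(y).value_counts()
    if (counts < 3).any():
        raise ValueError("stratified threefold CV needs >= 3 samples per class")
    rng = np.random.default_rng(seed)

    probs = np.zeros((0, len(classes)))
    truth: list[str] = []
    coef_abs = np.zeros(X.shape[1])
    n_models = 0
    fold_rows = []
    for rep in range(n_repeats):
        outer = StratifiedKFold(n_splits=3, shuffle=True,
                                random_state=int(rng.integers(2**31 - 1)))
        for fold, (tr, te) in enumerate(outer.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            best_C, best_score = Cs[0], -np.inf
            inner = StratifiedKFold(n_splits=2, shuffle=True,
                                    random_state=int(rng.integers(2**31 - 1)))
            inner_state = int(rng.integers(2**31 - 1))
            for C in Cs:
                score = 0.0
                for itr, ite in inner.split(Xtr, y[tr]):
                    m = _enet(C, alpha_mix, inner_state).fit(Xtr[itr], y[tr][itr])
                    score += m.score(Xtr[ite], y[tr][ite])
                if score > best_score:
                    best_score, best_C = score, C
            model = _enet(best_C, alpha_mix, inner_state).fit(Xtr, y[tr])
            pr = model.predict_proba(Xte)
            aligned = np.zeros((len(te), len(classes)))
            for k, c in enumerate(model.classes_):
                aligned[:, classes.index(c)] = pr[:, k]
            probs = np.vstack([probs, aligned])
            truth.extend(y[te].tolist())
            coef_abs += np.abs(model.coef_).mean(axis=0)
            n_models += 1
            for s in te:
                fold_rows.append({"repeat": rep, "fold": fold,
                                  "sample_id": design.sample_ids[s]})

    truth_arr = np.array(truth)
    pred = np.array(classes)[probs.argmax(axis=1)]
    acc = float((pred == truth_arr).mean())
    f1 = float(f1_score(truth_arr, pred, average="macro"))
    try:
        auc = float(
            roc_auc_score(truth_arr, probs, multi_class="ovr",
                          average="macro", labels=classes)
        )
    except ValueError:
        auc = float("nan")
    counts_mat = confusion_matrix(truth_arr, pred, labels=classes)
    conf_counts = pd.DataFrame(counts_mat, index=classes, columns=classes)
    row_sums = counts_mat.sum(axis=1, keepdims=True)
    conf_pct = pd.DataFrame(
        np.where(row_sums > 0, counts_mat / row_sums * 100.0, 0.0),
        index=classes, columns=classes,
    )
    ranking = pd.Series(coef_abs / n_models, index=list(ffa.index)).sort_values(
        ascending=False
    )
    return ClassifierReport(
        classes=classes,
        confusion_counts=conf_counts,
        confusion_percent=conf_pct,
        accuracy=acc,
        macro_f1=f1,
        macro_auc=auc,
        coefficient_ranking=ranking,
        fold_assignments=pd.DataFrame(fold_rows),
    )


def _enet(C: float, l1_ratio: float, random_state: int = 0) -> LogisticRegression:
    return LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=C, max_iter=10_000, tol=1e-4,
        random_state=random_state,
    )
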