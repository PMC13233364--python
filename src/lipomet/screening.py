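"""Unified discriminant screening across the six pairwise regime contrasts.

A feature is a pairwise discriminant only when three criteria hold at once:
VIP > 1 from the contrast's two-class OPLS-DA, |log2FC| >= 1 between raw
group means, and two-sided t-test p < 0.05.  Tiering then distinguishes the
shared core (passing all three baseline-referenced contrasts A vs B/C/D),
regime-specific discriminants (unique to one baseline contrast), and
recurrent robust markers (passing at least five of the six contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import opls_da, preprocess
from .io import FeatureTable, SampleDesign

__all__ = [
    "CANONICAL_CONTRASTS",
    "BASELINE_CONTRASTS",
    "ContrastResult",
    "ScreenThresholds",
    "pairwise_contrast",
    "run_all_contrasts",
    "screen",
    "assign_tiers",
    "upset_counts",
]

CANONICAL_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
)
BASELINE_CONTRASTS: tuple[tuple[str, str], ...] = (("A", "B"), ("A", "C"), ("A", "D"))


@dataclass(frozen=True)
class ScreenThresholds:
    """Boundary semantics exactly as stated: VIP strictly > 1,
    |log2FC| >= 1 inclusive, p strictly < 0.05."""

    vip: float = 1.0
    abs_log2fc: float = 1.0
    p: float = 0.05


@dataclass
class ContrastResult:
    """Per-feature statistics for one ordered regime contrast."""

    first: str
    second: str
    table: pd.DataFrame  # index feature_id; columns vip, log2fc, p, pass

    @property
    def name(self) -> str:
        return f"{self.first}_vs_{self.second}"

    def passing(self) -> set[str]:
        return set(self.table.index[self.table["pass"]])


def _log2fc(mean_first: np.ndarray, mean_second: np.ndarray, epsilon: float) -> np.ndarray:
    """log2(mean_second / mean_first) with an epsilon guard on zero means."""
    a = mean_first.copy()
    b = mean_second.copy()
    zero = (a == 0) | (b == 0)
    a[zero] += epsilon
    b[zero] += epsilon
    return np.log2(b / a)


def pairwise_contrast(
    table: FeatureTable,
    design: SampleDesign,
    first: str,
    second: str,
    thresholds: ScreenThresholds | None = None,
    n_orthogonal: int = 1,
    equal_var: bool = True,
) -> ContrastResult:
    """Screen one regime pair: VIP, log2 fold change and t-test per feature.

    log2FC is computed on raw (untransformed) group means, second over
    first; when either mean is 0 both get an epsilon of 1e-3 times the
    smallest positive abundance in the table.  p is a two-sided two-sample
    t-test (pooled variance by default; Welch with ``equal_var=False``).
    VIP comes from a fresh two-class OPLS-DA (1 predictive + ``n_orthogonal``
    orthogonal components) on the autoscaled log2(abundance+1) matrix of the
    two groups' samples.
    """
    thresholds = thresholds or ScreenThresholds()
    stat = table.statistics_view()
    g1 = stat.values_by_regime(first)
    g2 = stat.values_by_regime(second)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("both regimes need at least 2 replicates")

    positive = stat.abundance.to_numpy()
    positive = positive[positive > 0]
    epsilon = (positive.min() if positive.size else 1.0) * 1e-3
    log2fc = _log2fc(g1.mean(axis=1), g2.mean(axis=1), epsilon)

    p = stats.ttest_ind(g1, g2, axis=1, equal_var=equal_var).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant and equal

    samples = design.samples_of(first) + design.samples_of(second)
    labels = [first] * len(design.samples_of(first)) + [second] * len(design.samples_of(second))
    sub = stat.abundance[samples]
    mat = preprocess(sub, transform="log2p1", scaling="unit-variance")
    model = opls_da(mat, labels, n_orthogonal=n_orthogonal, compute_q2=False)
    vip = pd.Series(model.vip, index=mat.feature_ids).reindex(stat.feature_ids).fillna(0.0)

    out = pd.DataFrame(
        {"vip": vip.to_numpy(), "log2fc": log2fc, "p": p}, index=stat.feature_ids
    )
    out["pass"] = (
        (out["vip"] > thresholds.vip)
        & (out["log2fc"].abs() >= thresholds.abs_log2fc)
        & (out["p"] < thresholds.p)
    )
    return ContrastResult(first, second, out)


def run_all_contrasts(
    table: FeatureTable,
    design: SampleDesign,
    thresholds: ScreenThresholds | None = None,
    **kwargs,
) -> dict[tuple[str, str], ContrastResult]:
    """All six canonical pairwise contrasts."""
    return {
        pair: pairwise_contrast(table, design, *pair, thresholds=thresholds, **kwargs)
        for pair in CANONICAL_CONTRASTS
    }


def screen(result: ContrastResult) -> set[str]:
    """The discriminant feature set of one contrast (pass = all 3 criteria)."""
    return result.passing()


def assign_tiers(
    results: dict[tuple[str, str], ContrastResult] | list[ContrastResult],
) -> pd.DataFrame:
    """Assemble shared-core, regime-specific and recurrence tiers.

    Requires exactly the six canonical contrasts.  Per feature:

    - ``core_a``: passes all three A-referenced contrasts;
    - ``specific_to``: the single A-referenced contrast passed (B/C/D), or
      ``none`` (mutually exclusive with core_a by construction);
    - ``recurrence``: number of the six contrasts passed (the >= 5 tier is
      the recurrent robust marker set);
    - ``direction_consistent``: same log2FC sign in every A-referenced
      contrast the feature passed (a single pass is trivially consistent);
    - ``max_vip`` / ``min_p`` over the A-referenced contrasts.
    """
    if isinstance(results, list):
        results = {(r.first, r.second): r for r in results}
    missing = [p for p in CANONICAL_CONTRASTS if p not in results]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")

    index = results[CANONICAL_CONTRASTS[0]].table.index
    pass_mat = pd.DataFrame(
        {p: results[p].table["pass"].reindex(index) for p in CANONICAL_CONTRASTS}
    )
    recurrence = pass_mat.sum(axis=1).astype(int)

    base = list(BASELINE_CONTRASTS)
    base_pass = pass_mat[base]
    core_a = base_pass.all(axis=1)
    n_base = base_pass.sum(axis=1)
    specific = pd.Series("none", index=index, dtype=object)
    for pair in base:
        only = (n_base == 1) & base_pass[pair]
        specific[only] = pair[1]

    signs = pd.DataFrame(
        {p: np.sign(results[p].table["log2fc"].reindex(index)) for p in base}
    )
    masked = signs.where(base_pass)
    direction_consistent = masked.apply(
        lambda row: bool(row.dropna().nunique() <= 1), axis=1
    )
    max_vip = pd.DataFrame(
        {p: results[p].table["vip"].reindex(index) for p in base}
    ).max(axis=1)
    min_p = pd.DataFrame(
        {p: results[p].table["p"].reindex(index) for p in base}
    ).min(axis=1)

    out = pd.DataFrame(
        {
            "core_a": core_a,
            "specific_to": specific,
            "recurrence": recurrence,
            "direction_consistent": direction_consistent,
            "max_vip": max_vip,
            "min_p": min_p,
        },
        index=index,
    )
    out.index.name = "feature_id"
    return out


def upset_counts(pass_sets: dict[str, set[str]] | list[set[str]]) -> dict[tuple[int, ...], int]:
    """Exact sizes of all nonempty membership patterns over the given sets.

    Keys are binary membership tuples in set order, e.g. for three sets
    ``(1, 1, 1)`` is the triple intersection and ``(1, 0, 0)`` the features
    exclusive to the first set.
    """
    if isinstance(pass_sets, dict):
        sets = list(pass_sets.values())
    else:
        sets = list(pass_sets)
    universe = set().union(*sets) if sets else set()
    counts: dict[tuple[int, ...], int] = {}
    for feat in universe:
        key = tuple(int(feat in s) for s in sets)
        counts[key] = counts.get(key, 0) + 1
    return counts
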