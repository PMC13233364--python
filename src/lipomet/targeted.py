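"""Targeted free-fatty-acid layer: calibration, quantification and statistics.

Covers the GC–MS quantification chain — weighted linear calibration of
analyte/internal-standard area ratios, back-calculation, conversion to
fresh-weight content, QC gating — and the regime-level statistics on the
resulting species x samples concentration table: detection filtering,
mean/SEM/CV summaries with one-way ANOVA and Tukey HSD compact letters, and
the derived saturation metrics (SFA/MUFA/PUFA fractions, oleic/linoleic
shares, O/L ratio).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGIMES, SampleDesign

__all__ = [
    "CalibrationCurve",
    "VolumeConstants",
    "RegimeSummary",
    "fit_calibration",
    "back_calculate",
    "compute_content",
    "qc_evaluate",
    "calibration_qc_ledger",
    "detection_filter",
    "regime_summaries",
    "summarize_metric",
    "ffa_metrics",
    "tukey_letters",
    "parse_acyl",
]

_ACYL_RE = re.compile(r"(\d+):(\d+)")


def parse_acyl(species: str) -> tuple[int, int]:
    """Extract (carbons, double_bonds) from an acyl descriptor like '18:1'."""
    m = _ACYL_RE.search(species)
    if not m:
        raise ValueError(f"no acyl descriptor (carbons:double_bonds) in {species!r}")
    return int(m.group(1)), int(m.group(2))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    weighting: str  # "1/x" or "1/x2"
    r_squared: float
    linear_range: tuple[float, float]


def _weights(conc: np.ndarray, weighting: str) -> np.ndarray:
    if weighting in ("1/x", "1/x^1"):
        return 1.0 / conc
    if weighting in ("1/x2", "1/x^2", "1/x²"):
        return 1.0 / conc**2
    if weighting in ("none", "1"):
        return np.ones_like(conc)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_calibration(
    points: list[tuple[float, float]] | pd.DataFrame,
    weighting: str = "1/x2",
    analyte: str = "",
) -> CalibrationCurve:
    """Weighted linear fit of area ratio on concentration.

    Minimises sum w_i (y_i - a x_i - b)^2 with w_i = 1/x_i or 1/x_i^2.
    The reported R^2 is computed on weighted residuals about the weighted
    mean: R^2 = 1 - SSE_w / SST_w.
    """
    if isinstance(points, pd.DataFrame):
        conc = points["conc"].to_numpy(dtype=float)
        y = points["area_ratio"].to_numpy(dtype=float)
    else:
        conc = np.array([p[0] for p in points], dtype=float)
        y = np.array([p[1] for p in points], dtype=float)
    if len(conc) < 3:
        raise ValueError("at least 3 calibration points are required")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive for 1/x-family weights")
    if np.allclose(conc, conc[0]):
        raise ValueError("singular fit: all concentrations equal")
    w = _weights(conc, weighting)
    sw = w.sum()
    xbar = (w * conc).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (conc - xbar) ** 2).sum()
    sxy = (w * (conc - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    sse = (w * (y - slope * conc - intercept) ** 2).sum()
    sst = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        r_squared=float(r2),
        linear_range=(float(conc.min()), float(conc.max())),
    )


def back_calculate(
    area_ratio: float | np.ndarray, curve: CalibrationCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Invert a calibration curve: Cs = (ratio - intercept) / slope.

    Values falling below zero (ratio under the intercept) are clamped to 0
    and flagged.  Returns ``(concentration, below_range_flag)`` arrays.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    ratio = np.atleast_1d(np.asarray(area_ratio, dtype=float))
    cs = (ratio - curve.intercept) / curve.slope
    below = cs < 0
    return np.where(below, 0.0, cs), below


@dataclass(frozen=True)
class VolumeConstants:
    """Extraction/derivatization volumes for the fresh-weight content formula.

    V1 is the reconstitution volume in mL; V2 the total extraction-solvent
    volume and V3 the derivatized aliquot, both in uL (their units cancel);
    M the sample fresh mass in mg.
    """

    V1: float = 0.16   # mL
    V2: float = 1000.0  # uL
    V3: float = 800.0   # uL

    def __post_init__(self):
        if min(self.V1, self.V2, self.V3) <= 0:
            raise ValueError("volumes must be positive")


def compute_content(
    cs: float | np.ndarray, mass_mg: float, vols: VolumeConstants | None = None
) -> np.ndarray | float:
    """Fresh-weight FFA content: C_con = Cs * V1 * V2 / (M * V3) in ng mg^-1."""
    vols = vols or VolumeConstants()
    if mass_mg <= 0:
        raise ValueError("sample mass must be positive")
    return np.asarray(cs, dtype=float) * vols.V1 * vols.V2 / (mass_mg * vols.V3)


def qc_evaluate(
    measurements: np.ndarray | list[float], nominal: float
) -> dict:
    """Accuracy/precision gate for QC injections of one analyte.

    accuracy = mean/nominal, RSD = SD/mean (ddof=1); pass iff accuracy in
    [0.80, 1.20] and RSD <= 0.20, both bounds inclusive.
    """
    if nominal <= 0:
        raise ValueError("nominal QC concentration must be positive")
    x = np.asarray(measurements, dtype=float)
    if len(x) < 2:
        raise ValueError("at least 2 QC measurements are required")
    mean = x.mean()
    accuracy = mean / nominal
    rsd = float(x.std(ddof=1) / mean) if mean > 0 else np.inf
    ok = bool(0.80 <= accuracy <= 1.20 and rsd <= 0.20)
    return {"accuracy": float(accuracy), "rsd": rsd, "pass": ok}


def calibration_qc_ledger(
    points: pd.DataFrame,
    qc: pd.DataFrame,
    qc_nominal: float,
    weighting: str = "1/x2",
) -> pd.DataFrame:
    """Fit every analyte's curve, back-calculate its QC injections, gate them.

    Returns one row per analyte with slope, intercept, weighted R^2,
    accuracy, RSD and verdict — the QC ledger.
    """
    rows = []
    for analyte, grp in points.groupby("analyte", sort=False):
        curve = fit_calibration(grp, weighting=weighting, analyte=str(analyte))
        ratios = qc.loc[qc["analyte"] == analyte, "area_ratio"].to_numpy()
        conc, _ = back_calculate(ratios, curve)
        verdict = qc_evaluate(conc, qc_nominal)
        rows.append(
            {
                "analyte": analyte,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "accuracy": verdict["accuracy"],
                "rsd": verdict["rsd"],
                "pass": verdict["pass"],
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


# ---------------------------------------------------------------------------
# Concentration-table statistics
# ---------------------------------------------------------------------------


def detection_filter(table: pd.DataFrame) -> pd.Series:
    """Boolean detected flag: concentration > 0 in at least one sample."""
    return (table > 0).any(axis=1)


def _tukey_decisions(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pairwise Tukey HSD decision matrix from studentized-range quantiles.

    Returns (significant[k,k], p[k,k], mse).  Uses the Tukey–Kramer
    statistic q = |mi - mj| / sqrt(MSE/2 * (1/ni + 1/nj)) against the
    studentized range distribution with k groups and N-k error df.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    dferr = int(ns.sum() - k)
    if dferr <= 0:
        raise ValueError("no error degrees of freedom for Tukey HSD")
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / dferr
    sig = np.zeros((k, k), dtype=bool)
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / np.sqrt(
                    mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])
                )
                p = float(stats.studentized_range.sf(q, k, dferr))
            pmat[i, j] = pmat[j, i] = p
            sig[i, j] = sig[j, i] = p < alpha
    return sig, pmat, mse


def tukey_letters(sig: np.ndarray, labels: list[str]) -> dict[str, str]:
    """Compact letter display from a pairwise significance matrix.

    Insert-and-absorb construction: two groups share a letter iff they are
    not significantly different, which is exactly the Tukey decision matrix.
    """
    k = len(labels)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    columns.extend([col - {i}, col - {j}])
            # absorb columns that are subsets of another
            columns = [
                c
                for idx, c in enumerate(columns)
                if c and not any(c < d or (c == d and idx2 < idx)
                                 for idx2, d in enumerate(columns) if idx2 != idx)
            ]
    # stable ordering: letter columns sorted by their smallest member
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, col in zip(alphabet, columns):
        for i in sorted(col):
            out[labels[i]] += letter
    return out


@dataclass
class RegimeSummary:
    """Per-regime mean/SEM/CV with ANOVA and Tukey letters for one metric."""

    metric: str
    stats: pd.DataFrame  # index regime; columns mean, sem, cv, n
    anova_p: float
    anova_f: float
    letters: dict[str, str]
    tukey_p: pd.DataFrame  # regime x regime pairwise p


def summarize_metric(
    per_sample: pd.Series, design: SampleDesign, metric: str = "metric",
    alpha: float = 0.05,
) -> RegimeSummary:
    """Regime summary (mean, SEM, CV), one-way ANOVA and Tukey HSD letters."""
    design.require_replication(2)
    regimes = list(design.regime_levels)
    groups = [per_sample.loc[design.samples_of(r)].to_numpy(dtype=float) for r in regimes]
    rows = []
    for r, g in zip(regimes, groups):
        mean = g.mean()
        sd = g.std(ddof=1)
        rows.append(
            {
                "regime": r,
                "mean": mean,
                "sem": sd / np.sqrt(len(g)),
                "cv": sd / mean if mean != 0 else np.nan,
                "n": len(g),
            }
        )
    stats_df = pd.DataFrame(rows).set_index("regime")
    if all(np.allclose(g, groups[0][0]) for g in groups):
        f, p = 0.0, 1.0  # identical samples: no variance anywhere
    else:
        f, p = stats.f_oneway(*groups)
    sig, pmat, _ = _tukey_decisions(groups, alpha=alpha)
    letters = tukey_letters(sig, regimes)
    tukey_p = pd.DataFrame(pmat, index=regimes, columns=regimes)
    return RegimeSummary(metric, stats_df, float(p), float(f), letters, tukey_p)


def regime_summaries(
    table: pd.DataFrame, design: SampleDesign, per_species: bool = True
) -> dict[str, RegimeSummary]:
    """Summaries for total FFA (over detected species) and each detected species."""
    detected = detection_filter(table)
    totals = table.loc[detected].sum(axis=0)
    out = {"total": summarize_metric(totals, design, "total")}
    if per_species:
        for sp in table.index[detected]:
            out[sp] = summarize_metric(table.loc[sp], design, sp)
    return out


def ffa_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample FFA-derived metrics from acyl descriptors.

    Columns: total (over detected species), SFA/MUFA/PUFA percentage of the
    detected total, oleic (18:1) and linoleic (18:2) percentages, and the
    O/L ratio (NaN-flagged where linoleic is 0).
    """
    detected = detection_filter(table)
    det = table.loc[detected]
    db = np.array([parse_acyl(s)[1] for s in det.index])
    total = det.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sfa = det.loc[db == 0].sum(axis=0) / total * 100.0
        mufa = det.loc[db == 1].sum(axis=0) / total * 100.0
        pufa = det.loc[db >= 2].sum(axis=0) / total * 100.0
    carbons_db = [(parse_acyl(s)) for s in det.index]
    oleic_rows = [s for s, cd in zip(det.index, carbons_db) if cd == (18, 1)]
    linoleic_rows = [s for s, cd in zip(det.index, carbons_db) if cd == (18, 2)]
    oleic = det.loc[oleic_rows].sum(axis=0)
    linoleic = det.loc[linoleic_rows].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ol = np.where(linoleic > 0, oleic / linoleic, np.nan)
    out = pd.DataFrame(
        {
            "total": total,
            "SFA_pct": sfa,
            "MUFA_pct": mufa,
            "PUFA_pct": pufa,
            "oleic_pct": oleic / total * 100.0,
            "linoleic_pct": linoleic / total * 100.0,
            "OL_ratio": ol,
        }
    )
    out.index.name = "sample_id"
    return out
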