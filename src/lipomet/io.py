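"""Tabular input/output, design validation, run configuration and RT QC.

The pipeline exchanges plain delimited text: a features x samples abundance
table with fixed-name annotation columns, and a sample-design table mapping
samples to postharvest regimes (A–D) and biological replicates.  Files are
UTF-8 and tab-delimited by default, with a comma fallback.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SampleDesign",
    "FeatureTable",
    "RtqcReport",
    "read_sample_design",
    "read_feature_table",
    "write_feature_table",
    "rtqc_check",
    "load_config",
    "get_logger",
]

REGIMES = ("A", "B", "C", "D")

#: Annotation columns recognised in a feature table, in canonical order.
ANNOTATION_COLUMNS = ("msi_level", "superclass", "class", "lipid_class")

logger = logging.getLogger("lipomet")


def get_logger(run_seed: int | None = None, config: Mapping | None = None) -> logging.Logger:
    """Return the package logger with a stderr handler attached once.

    When ``run_seed``/``config`` are given they are echoed so a run can be
    reproduced from its log alone.
    """
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s lipomet: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if run_seed is not None:
        logger.info("run seed = %d", run_seed)
    if config is not None:
        logger.info("config = %r", dict(config))
    return logger


class DesignError(ValueError):
    """A sample design (or table/design pairing) violates an invariant."""


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of sample ids to regime (A/B/C/D) and replicate number."""

    sample_ids: tuple[str, ...]
    regimes: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self):
        if len(self.sample_ids) != len(set(self.sample_ids)):
            dupes = [s for s in self.sample_ids if list(self.sample_ids).count(s) > 1]
            raise DesignError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad = sorted(set(self.regimes) - set(REGIMES))
        if bad:
            raise DesignError(f"unknown regime labels: {bad} (expected one of {REGIMES})")
        if any(r < 1 for r in self.replicates):
            raise DesignError("replicate numbers must be positive integers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def regime_levels(self) -> tuple[str, ...]:
        return tuple(r for r in REGIMES if r in self.regimes)

    def samples_of(self, regime: str) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.regimes) if r == regime]

    def regime_of(self) -> pd.Series:
        return pd.Series(self.regimes, index=list(self.sample_ids), name="regime")

    def require_replication(self, minimum: int = 2) -> None:
        """Raise unless every regime present has at least ``minimum`` replicates."""
        counts = pd.Series(self.regimes).value_counts()
        thin = counts[counts < minimum]
        if len(thin):
            raise DesignError(
                f"regimes with fewer than {minimum} replicates: {dict(thin)}"
            )

    @classmethod
    def default(cls) -> "SampleDesign":
        """The study layout: 4 regimes x 3 biological replicates."""
        ids, regs, reps = [], [], []
        for r in REGIMES:
            for k in (1, 2, 3):
                ids.append(f"{r}{k}")
                regs.append(r)
                reps.append(k)
        return cls(tuple(ids), tuple(regs), tuple(reps))


@dataclass
class FeatureTable:
    """Features x samples abundance matrix plus per-feature annotation.

    ``abundance`` is indexed by feature_id with sample columns matching the
    design; ``annotation`` carries msi_level (1–4), superclass, class and an
    optional lipid_class code.  Features annotated beyond MSI level 2 are kept
    for reporting but flagged for exclusion from statistics.
    """

    abundance: pd.DataFrame
    annotation: pd.DataFrame
    design: SampleDesign

    def __post_init__(self):
        if self.abundance.index.has_duplicates:
            dupes = self.abundance.index[self.abundance.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        missing = [s for s in self.design.sample_ids if s not in self.abundance.columns]
        if missing:
            raise DesignError(f"table is missing design sample columns: {missing}")
        self.abundance = self.abundance.loc[:, list(self.design.sample_ids)]
        vals = self.abundance.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("abundances must be finite")
        if (vals < 0).any():
            raise ValueError("abundances must be nonnegative")
        self.annotation = self.annotation.reindex(self.abundance.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def n_features(self) -> int:
        return len(self.abundance)

    @property
    def statistics_mask(self) -> pd.Series:
        """True for features eligible for statistics (MSI level 1 or 2)."""
        lvl = pd.to_numeric(self.annotation["msi_level"], errors="coerce")
        return lvl.isin([1, 2])

    def statistics_view(self) -> "FeatureTable":
        """Restrict to the MSI level 1–2 matrix used for all statistics."""
        keep = self.statistics_mask
        return FeatureTable(
            self.abundance.loc[keep].copy(), self.annotation.loc[keep].copy(), self.design
        )

    def values_by_regime(self, regime: str) -> np.ndarray:
        """features x replicates array for one regime."""
        return self.abundance[self.design.samples_of(regime)].to_numpy(dtype=float)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 delimited file: tab first, comma fallback."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    if df.shape[1] == 1 and "," in df.columns[0]:
        df = pd.read_csv(path, sep=",", dtype=str, encoding="utf-8")
    return df


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a design table with columns sample_id, regime, replicate."""
    df = _read_delimited(path)
    required = {"sample_id", "regime", "replicate"}
    if not required.issubset(df.columns):
        raise DesignError(f"design file must have columns {sorted(required)}")
    try:
        reps = tuple(int(x) for x in df["replicate"])
    except (TypeError, ValueError) as exc:
        raise DesignError(f"non-integer replicate value: {exc}") from exc
    return SampleDesign(tuple(df["sample_id"]), tuple(df["regime"]), reps)


def read_feature_table(path: str | Path, design: SampleDesign) -> FeatureTable:
    """Read and validate a feature table against a design.

    The first column is feature_id; annotation columns are taken by fixed
    names; every design sample must appear as a column.  Missing abundance
    cells are read as 0 (non-detections carry no signal) and logged.
    """
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    ann_cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    annotation = df[ann_cols].copy()
    if "msi_level" in annotation:
        annotation["msi_level"] = pd.to_numeric(annotation["msi_level"], errors="coerce")
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise DesignError(f"feature table at {path} is missing sample columns {missing}")
    raw = df[list(design.sample_ids)]
    n_missing = int(raw.isna().sum().sum())
    if n_missing:
        get_logger().warning("%d missing abundance cells read as 0", n_missing)
    def _parse(cell):
        # python float() is correctly rounded (pandas' fast parser is not),
        # keeping write->read round-trips bit-exact
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return 0.0
        return float(cell)

    try:
        abundance = raw.map(_parse)
    except (TypeError, ValueError):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & raw.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric abundance at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    table = FeatureTable(abundance, annotation, design)
    n_excl = int((~table.statistics_mask).sum())
    if n_excl:
        get_logger().info("%d features beyond MSI level 2 excluded from statistics", n_excl)
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV; round-trips abundances bit-exactly."""
    ann = table.annotation.copy()
    out = pd.concat([ann, table.abundance], axis=1)
    out.index.name = "feature_id"
    # repr-precision floats so read_feature_table reproduces values bit-exactly
    out.to_csv(path, sep="\t", float_format="%.17g", encoding="utf-8")


@dataclass(frozen=True)
class RtqcReport:
    """Retention-time QC outcome over a marker panel."""

    markers: tuple[str, ...]
    deviations: np.ndarray  # seconds, |observed - reference|
    slope: float
    r_squared: float
    threshold: float
    pass_flag: bool


def rtqc_check(
    reference_rt: Mapping[str, float] | Sequence[float],
    observed_rt: Mapping[str, float] | Sequence[float],
    threshold: float = 30.0,
) -> RtqcReport:
    """Check retention-time stability of repeated QC-marker injections.

    Deviations are ``|observed - reference|`` per marker; an OLS fit of
    observed on reference supplies slope and R².  The run passes iff every
    deviation is strictly below ``threshold`` seconds.
    """
    if isinstance(reference_rt, Mapping):
        markers = tuple(reference_rt)
        ref = np.array([reference_rt[m] for m in markers], dtype=float)
        obs = np.array([observed_rt[m] for m in markers], dtype=float)
    else:
        ref = np.asarray(reference_rt, dtype=float)
        obs = np.asarray(observed_rt, dtype=float)
        markers = tuple(f"marker{i+1}" for i in range(len(ref)))
    if len(ref) != len(obs):
        raise ValueError("reference and observed marker panels differ in length")
    if len(ref) < 2:
        raise ValueError("rtqc_check needs at least 2 markers")
    dev = np.abs(obs - ref)
    fit = stats.linregress(ref, obs)
    r2 = float(fit.rvalue**2)
    return RtqcReport(
        markers=markers,
        deviations=dev,
        slope=float(fit.slope),
        r_squared=r2,
        threshold=float(threshold),
        pass_flag=bool((dev < threshold).all()),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file as a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return dict(cfg or {})
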