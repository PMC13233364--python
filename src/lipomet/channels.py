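"""Dual-channel lipid-class summaries of the annotated untargeted lipidome.

Two channels of annotated features frame the free-fatty-acid phenotype:
membrane glycerophospholipids (PC/PE/PG/PI/PS/PA/CL) against their
single-acyl lyso forms, and the neutral acylglycerols (TAG/DAG/MAG).
Regime-wise channel totals are expressed as log2 fold-changes relative to
the baseline regime (clipped at +/-4 for display, with an unclipped log10
audit view), together with the Lyso/GPL ratio and per-sample composite
indices.  These are semi-quantitative, annotation-derived summaries, not
absolute lipid quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleDesign

__all__ = [
    "ChannelMap",
    "ChannelSummary",
    "classify_lipids",
    "channel_summary",
    "composite_indices",
]

GPL_CLASSES = ("PC", "PE", "PG", "PI", "PS", "PA", "CL")
LYSO_CLASSES = ("LPC", "LPE", "LPG", "LPI", "LPS", "LPA")
NEUTRAL_CLASSES = ("TAG", "DAG", "MAG")


@dataclass(frozen=True)
class ChannelMap:
    """Deterministic lipid_class -> channel mapping; unmapped classes are
    reported, never silently dropped.  Lyso recognition also accepts
    "L"-prefixed GPL codes via the alias rule plus a configurable list."""

    gpl: tuple[str, ...] = GPL_CLASSES
    lyso: tuple[str, ...] = LYSO_CLASSES
    neutral: tuple[str, ...] = NEUTRAL_CLASSES
    lyso_aliases: tuple[str, ...] = ()

    def channel_of(self, lipid_class: str | None) -> str:
        if lipid_class is None or lipid_class == "" or pd.isna(lipid_class):
            return ""
        cls = str(lipid_class)
        if cls in self.gpl:
            return "GPL"
        if cls in self.lyso or cls in self.lyso_aliases:
            return "Lyso-GPL"
        if cls.startswith("L") and cls[1:] in self.gpl:
            return "Lyso-GPL"
        if cls in self.neutral:
            return "neutral"
        return "unmapped"


def classify_lipids(
    table: FeatureTable, channel_map: ChannelMap | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each feature a channel label and report coverage.

    Returns ``(labels, coverage)``: labels are "" for features without a
    lipid_class annotation and "unmapped" for lipid classes outside the
    map; coverage counts lipid-annotated features per channel and the
    mapped fraction.
    """
    channel_map = channel_map or ChannelMap()
    lipid_cls = table.annotation.get("lipid_class")
    if lipid_cls is None:
        raise ValueError("feature table has no lipid_class annotation column")
    labels = lipid_cls.map(channel_map.channel_of).fillna("")
    annotated = labels != ""
    rows = []
    for chan in ("GPL", "Lyso-GPL", "neutral", "unmapped"):
        n = int((labels == chan).sum())
        rows.append({"channel": chan, "n_features": n,
                     "fraction_of_annotated": n / annotated.sum() if annotated.any() else 0.0})
    coverage = pd.DataFrame(rows).set_index("channel")
    return labels, coverage


@dataclass
class ChannelSummary:
    """Regime-wise channel totals, baseline log2 fold-changes and ratios."""

    baseline: str
    totals: pd.DataFrame        # channel x regime, mean over replicate sums
    log2fc: pd.DataFrame        # channel x regime, vs baseline (baseline col = 0)
    log2fc_clipped: pd.DataFrame
    lyso_gpl_ratio: pd.Series   # per regime
    audit_log10: pd.DataFrame   # log10 of raw totals
    clip: float
    flags: pd.DataFrame         # zero-baseline / clipping flags


def channel_summary(
    table: FeatureTable,
    design: SampleDesign,
    labels: pd.Series,
    baseline: str = "A",
    clip: float = 4.0,
) -> ChannelSummary:
    """Summarise channel abundance per regime against the baseline.

    The regime total of a channel is the mean over replicates of the
    within-sample feature sum (replicate-count invariant); log2fc is
    log2(total / baseline total), clipped at +/-clip for display, with the
    raw value retained in the log10 audit view.
    """
    if baseline not in design.regime_levels:
        raise ValueError(f"baseline regime {baseline!r} absent from design")
    channels = [c for c in ("GPL", "Lyso-GPL", "neutral") if (labels == c).any()]
    regimes = list(design.regime_levels)
    totals = pd.DataFrame(index=channels, columns=regimes, dtype=float)
    for chan in channels:
        feats = labels.index[labels == chan]
        sub = table.abundance.loc[feats]
        per_sample = sub.sum(axis=0)
        for r in regimes:
            totals.loc[chan, r] = per_sample[design.samples_of(r)].mean()

    base = totals[baseline]
    flags = pd.DataFrame("", index=channels, columns=regimes)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(totals.div(base, axis=0))
    for chan in channels:
        if base[chan] == 0:
            log2fc.loc[chan] = np.nan
            flags.loc[chan] = "zero-baseline"
    log2fc[baseline] = np.where(base > 0, 0.0, np.nan)  # exact 0 at baseline
    clipped = log2fc.clip(lower=-clip, upper=clip)
    flags = flags.mask((log2fc.abs() > clip) & (flags == ""), "clipped")

    if "GPL" in channels and "Lyso-GPL" in channels:
        ratio = totals.loc["Lyso-GPL"] / totals.loc["GPL"]
    else:
        ratio = pd.Series(np.nan, index=regimes)
    with np.errstate(divide="ignore"):
        audit = np.log10(totals.astype(float))
    return ChannelSummary(
        baseline=baseline,
        totals=totals,
        log2fc=log2fc,
        log2fc_clipped=clipped,
        lyso_gpl_ratio=ratio,
        audit_log10=audit,
        clip=clip,
        flags=flags,
    )


def composite_indices(
    table: FeatureTable, design: SampleDesign, labels: pd.Series
) -> pd.DataFrame:
    """Per-sample hydrolysis and acyl-editing indices.

    Operational definitions (the channels' Z-scores are per-feature Z of
    log2(abundance+1) across samples): hydrolysis index = mean Lyso-GPL Z
    minus mean GPL Z; acyl-editing index = mean Z over the union of both
    membrane channels.  Exported as explicitly operational composites.
    """
    gpl = labels.index[labels == "GPL"]
    lyso = labels.index[labels == "Lyso-GPL"]
    if len(gpl) == 0 or len(lyso) == 0:
        raise ValueError("both GPL and Lyso-GPL channels must be nonempty")
    logged = np.log2(table.abundance.loc[:, list(design.sample_ids)] + 1.0)
    z = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    hydrolysis = z.loc[lyso].mean(axis=0) - z.loc[gpl].mean(axis=0)
    acyl_editing = z.loc[list(gpl) + list(lyso)].mean(axis=0)
    out = pd.DataFrame(
        {"hydrolysis_index": hydrolysis, "acyl_editing_index": acyl_editing}
    )
    out.index.name = "sample_id"
    return out
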