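"""Synthetic targeted and untargeted datasets with known ground truth.

Every downstream stage of the pipeline is exercised on data generated here.
The defaults encode the study conditions: four postharvest regimes
(A baseline, B hot–humid holding, C 100 MPa + holding, D 500 MPa + holding)
with three biological replicates each; a 49-species targeted free-fatty-acid
panel of which seven species are undetectable; regime totals of 247.50,
220.47, 380.59 and 2401.41 ng mg^-1 FW with ~2% within-regime CV; and a
2,142-feature annotated metabolome carrying planted discriminant tiers
(25 shared-core, 47/45/138 regime-specific, 29 recurrent markers of which
5 separate every regime pair) plus sub-threshold membrane-lipid channel
trends (glycerophospholipids down, lyso-glycerophospholipids up, strongest
under 500 MPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import REGIMES, FeatureTable, SampleDesign

__all__ = [
    "TargetedPreset",
    "PlantConfig",
    "CalibrationFixture",
    "generate_targeted",
    "generate_untargeted",
    "generate_calibration",
]

# ---------------------------------------------------------------------------
# Targeted layer
# ---------------------------------------------------------------------------

#: 49-species free fatty acid panel, keyed by acyl descriptor carbons:double_bonds.
_SFA = [f"FFA {c}:0" for c in range(4, 25)]  # 4:0 .. 24:0, 21 species
_MUFA = [f"FFA {c}:1" for c in (14, 15, 16, 17, 18, 20, 22, 24)]  # 8 species
_PUFA = [
    "FFA 16:2", "FFA 16:3", "FFA 18:2", "FFA 18:3", "FFA 18:4",
    "FFA 20:2", "FFA 20:3", "FFA 20:4", "FFA 20:5", "FFA 21:2",
    "FFA 22:2", "FFA 22:3", "FFA 22:4", "FFA 22:5", "FFA 22:6",
    "FFA 24:2", "FFA 24:3", "FFA 24:4", "FFA 24:5", "FFA 24:6",
]  # 20 species
SPECIES_PANEL: tuple[str, ...] = tuple(_SFA + _MUFA + _PUFA)

#: Long-chain polyunsaturates absent from the seed matrix.
DEFAULT_UNDETECTABLE: tuple[str, ...] = (
    "FFA 18:4", "FFA 20:5", "FFA 22:5", "FFA 22:6",
    "FFA 24:4", "FFA 24:5", "FFA 24:6",
)


def _composition_weights() -> tuple[dict[str, float], dict[str, float]]:
    """Within-pool weights for the unsaturated and saturated fractions.

    Oleic (18:1) dominates, linoleic (18:2) second — the oil-tea seed
    free-acyl profile — with the remaining mass spread over minor species.
    Weights cover detectable species only and sum to 1 within each pool.
    """
    unsat = {s: 0.0 for s in _MUFA + _PUFA if s not in DEFAULT_UNDETECTABLE}
    major_u = {"FFA 18:1": 0.60, "FFA 18:2": 0.27, "FFA 18:3": 0.05,
               "FFA 16:1": 0.03, "FFA 20:1": 0.02}
    rest_u = [s for s in unsat if s not in major_u]
    for s, w in major_u.items():
        unsat[s] = w
    for s in rest_u:
        unsat[s] = 0.03 / len(rest_u)

    sat = {s: 0.0 for s in _SFA}
    major_s = {"FFA 16:0": 0.55, "FFA 18:0": 0.25, "FFA 20:0": 0.05,
               "FFA 14:0": 0.04, "FFA 12:0": 0.02, "FFA 22:0": 0.02,
               "FFA 24:0": 0.01}
    rest_s = [s for s in sat if s not in major_s]
    for s, w in major_s.items():
        sat[s] = w
    for s in rest_s:
        sat[s] = 0.06 / len(rest_s)
    return unsat, sat


@dataclass
class TargetedPreset:
    """Per-regime mean structure for the targeted FFA generator.

    Defaults reproduce the regime totals (ng mg^-1 FW) and the unsaturated
    fractions of the A and D pools; B and C fractions interpolate the
    A-to-D trend.
    """

    regime_totals: dict[str, float] = field(
        default_factory=lambda: {"A": 247.50, "B": 220.47, "C": 380.59, "D": 2401.41}
    )
    unsaturated_fraction: dict[str, float] = field(
        default_factory=lambda: {"A": 0.6329, "B": 0.6425, "C": 0.7150, "D": 0.7987}
    )
    cv: float = 0.02
    undetectable: tuple[str, ...] = DEFAULT_UNDETECTABLE
    n_replicates: int = 3

    def __post_init__(self):
        if any(t < 0 for t in self.regime_totals.values()):
            raise ValueError("regime totals must be nonnegative")
        if not (0 <= self.cv <= 0.03):
            raise ValueError("within-regime CV must lie in [0, 0.03]")
        unknown = set(self.undetectable) - set(SPECIES_PANEL)
        if unknown:
            raise ValueError(f"undetectable species not in panel: {sorted(unknown)}")

    def species_means(self) -> pd.DataFrame:
        """species x regime matrix of true mean concentrations (ng mg^-1 FW)."""
        unsat_w, sat_w = _composition_weights()
        means = pd.DataFrame(0.0, index=list(SPECIES_PANEL), columns=list(REGIMES))
        for r in REGIMES:
            total = self.regime_totals[r]
            u = self.unsaturated_fraction[r]
            for s, w in unsat_w.items():
                means.loc[s, r] = total * u * w
            for s, w in sat_w.items():
                means.loc[s, r] = total * (1 - u) * w
        means.loc[list(self.undetectable), :] = 0.0
        # renormalise detectable species so column sums hit the totals exactly
        for r in REGIMES:
            col = means[r]
            s = col.sum()
            if s > 0:
                means[r] = col * (self.regime_totals[r] / s)
        return means


def generate_targeted(
    preset: TargetedPreset | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a species x samples concentration table plus its truth record.

    Detectable concentrations are log-normal with the preset mean and CV
    (multiplicative noise keeps small-CV draws positive); undetectable
    species emit 0 everywhere.  Returns ``(table, truth)`` where ``truth``
    holds the per-regime true means.
    """
    if seed is None:
        raise ValueError("an explicit seed is required (reproducibility)")
    preset = preset or TargetedPreset()
    rng = np.random.default_rng(seed)
    design = _design(preset.n_replicates)
    means = preset.species_means()

    cols = list(design.sample_ids)
    table = pd.DataFrame(0.0, index=means.index, columns=cols)
    if preset.cv > 0:
        sigma = np.sqrt(np.log1p(preset.cv**2))  # log-normal sigma for target CV
        mu_adj = -0.5 * sigma**2  # keeps the arithmetic mean at the preset mean
    for sample, regime in zip(design.sample_ids, design.regimes):
        m = means[regime].to_numpy()
        if preset.cv > 0:
            noise = rng.lognormal(mean=mu_adj, sigma=sigma, size=len(m))
            table[sample] = m * noise
        else:
            table[sample] = m
    truth = means.copy()
    truth.index.name = "species"
    table.index.name = "species"
    return table, truth


def _design(n_replicates: int = 3) -> SampleDesign:
    ids, regs, reps = [], [], []
    for r in REGIMES:
        for k in range(1, n_replicates + 1):
            ids.append(f"{r}{k}")
            regs.append(r)
            reps.append(k)
    return SampleDesign(tuple(ids), tuple(regs), tuple(reps))


# ---------------------------------------------------------------------------
# Untargeted layer
# ---------------------------------------------------------------------------

#: Ten superclasses with proportions patterned on the level-1 annotation set.
SUPERCLASS_PROPORTIONS: dict[str, float] = {
    "Phenylpropanoids": 0.26,
    "Lipids": 0.20,
    "Amino acids and derivatives": 0.19,
    "Carbohydrates": 0.08,
    "Alkaloids": 0.07,
    "Terpenoids": 0.06,
    "Organic acids": 0.05,
    "Nucleotides and derivatives": 0.03,
    "Flavonoids": 0.03,
    "Others": 0.03,
}

#: Lipid-class composition of the channel-trend feature pool.
_CHANNEL_CLASSES: dict[str, int] = {
    # membrane glycerophospholipids
    "PC": 14, "PE": 12, "PG": 8, "PI": 8, "PS": 6, "PA": 6, "CL": 4,
    # lyso-glycerophospholipids
    "LPC": 10, "LPE": 8, "LPG": 5, "LPI": 5, "LPS": 4, "LPA": 4,
    # neutral acylglycerols
    "TAG": 10, "DAG": 8, "MAG": 6,
}

#: Sub-threshold per-regime log2 offsets for each lipid channel (A,B,C,D).
#: Magnitudes stay well below the |log2FC| >= 1 screening gate so channel
#: trends never contaminate the planted tier counts.
_CHANNEL_TRENDS: dict[str, tuple[float, float, float, float]] = {
    "GPL": (0.0, -0.08, -0.30, -0.70),
    "Lyso-GPL": (0.0, 0.08, 0.30, 0.70),
    "neutral": (0.0, 0.05, 0.18, 0.35),
}

_GPL = {"PC", "PE", "PG", "PI", "PS", "PA", "CL"}
_LYSO = {"LPC", "LPE", "LPG", "LPI", "LPS", "LPA"}


@dataclass
class PlantConfig:
    """Planted discriminant structure for the untargeted generator.

    Tier profiles are per-regime log2 offsets from a feature's base
    abundance (order A,B,C,D); each planted feature flips the whole profile
    with probability ``1 - p_up``.  Secondary sub-threshold shifts (the 0.7
    in the C/D-specific profiles, and the lipid-channel trends) emulate the
    correlated pressure response of real data without ever crossing the
    |log2FC| >= 1 screening gate.
    """

    n_features: int = 2142
    n_core_equal: int = 20      # shared core, identical shift in B/C/D
    n_all_six: int = 5          # shared core members separating every pair
    n_b_specific: int = 47
    n_c_specific: int = 45
    n_d_specific: int = 138
    n_five_of_six: int = 24     # tie A=B, separate C and D
    tier_profiles: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "core_shared": (0.0, 2.0, 2.0, 2.0),
            "all_six": (0.0, 2.5, 4.0, 6.5),
            "b_specific": (0.0, 2.0, 0.0, 0.0),
            "c_specific": (0.0, 0.0, 3.0, 0.7),
            "d_specific": (0.0, 0.0, 0.6, 2.5),
            "five_of_six": (0.0, 0.0, 2.5, 4.0),
        }
    )
    noise_cv: float = 0.05
    p_up: float = 0.7
    base_log10_mean: float = 5.0
    base_log10_sd: float = 0.45
    n_replicates: int = 3
    n_level1: int = 1338  # remaining features are annotated at MSI level 2
    seed: int = 0

    def __post_init__(self):
        counts = [self.n_core_equal, self.n_all_six, self.n_b_specific,
                  self.n_c_specific, self.n_d_specific, self.n_five_of_six]
        if any(c < 0 for c in counts):
            raise ValueError("tier counts must be nonnegative")
        n_channel = sum(_CHANNEL_CLASSES.values())
        if sum(counts) + n_channel > self.n_features:
            raise ValueError("planted + channel features exceed n_features")
        for tier, prof in self.tier_profiles.items():
            nz = [abs(v) for v in prof if v != 0.0]
            primary = max(nz, default=0.0)
            if nz and primary < 1.5:
                raise ValueError(
                    f"{tier}: primary effect {primary} below the 1.5 floor"
                )

    @property
    def n_planted(self) -> int:
        return (self.n_core_equal + self.n_all_six + self.n_b_specific
                + self.n_c_specific + self.n_d_specific + self.n_five_of_six)


def _tier_layout(config: PlantConfig) -> list[tuple[str, int]]:
    return [
        ("core_shared", config.n_core_equal),
        ("all_six", config.n_all_six),
        ("b_specific", config.n_b_specific),
        ("c_specific", config.n_c_specific),
        ("d_specific", config.n_d_specific),
        ("five_of_six", config.n_five_of_six),
    ]


def generate_untargeted(config: PlantConfig | None = None) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate an annotated feature table with planted discriminant tiers.

    Returns ``(table, truth)``.  ``truth`` records, per feature: tier label
    (``none`` for unplanted), shift direction, lipid channel membership and
    the number of regime pairs the planted profile is meant to separate.
    """
    config = config or PlantConfig()
    rng = np.random.default_rng(config.seed)
    design = _design(config.n_replicates)
    n = config.n_features
    width = len(str(n))
    feature_ids = [f"F{i+1:0{width}d}" for i in range(n)]

    # --- assemble per-feature tier labels, profiles, channels -------------
    tiers = ["none"] * n
    profiles = np.zeros((n, 4))
    channels = [""] * n
    lipid_class = [""] * n
    pos = 0
    for tier, count in _tier_layout(config):
        prof = np.array(config.tier_profiles[tier])
        for _ in range(count):
            tiers[pos] = tier
            profiles[pos] = prof
            pos += 1
    for cls, count in _CHANNEL_CLASSES.items():
        if cls in _GPL:
            chan = "GPL"
        elif cls in _LYSO:
            chan = "Lyso-GPL"
        else:
            chan = "neutral"
        prof = np.array(_CHANNEL_TRENDS[chan])
        for _ in range(count):
            channels[pos] = chan
            lipid_class[pos] = cls
            profiles[pos] = prof
            pos += 1
    # remaining features are pure nulls (one mean across regimes)

    directions = np.where(rng.random(n) < config.p_up, 1.0, -1.0)
    directions[np.array(tiers) == "none"] = 1.0  # sign is meaningless for nulls
    # channel features keep their planted sign (trend direction is the point)
    directions[np.array(channels) != ""] = 1.0

    base = 10.0 ** rng.normal(config.base_log10_mean, config.base_log10_sd, size=n)
    regime_means = base[:, None] * 2.0 ** (directions[:, None] * profiles)  # n x 4

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    mu_adj = -0.5 * sigma**2
    cols = {}
    for sample, regime in zip(design.sample_ids, design.regimes):
        ridx = REGIMES.index(regime)
        noise = rng.lognormal(mu_adj, sigma, size=n)
        cols[sample] = regime_means[:, ridx] * noise
    abundance = pd.DataFrame(cols, index=feature_ids)

    # --- annotation -------------------------------------------------------
    superclasses = np.array(list(SUPERCLASS_PROPORTIONS))
    probs = np.array(list(SUPERCLASS_PROPORTIONS.values()))
    probs = probs / probs.sum()
    sc = rng.choice(superclasses, size=n, p=probs)
    sc[np.array(lipid_class) != ""] = "Lipids"
    msi = np.full(n, 2, dtype=int)
    msi[rng.permutation(n)[: config.n_level1]] = 1
    annotation = pd.DataFrame(
        {
            "msi_level": msi,
            "superclass": sc,
            "class": np.where(np.array(lipid_class) != "", lipid_class, sc),
            "lipid_class": lipid_class,
        },
        index=feature_ids,
    )

    expected_recurrence = {
        "core_shared": 3, "all_six": 6, "b_specific": 3, "c_specific": 3,
        "d_specific": 3, "five_of_six": 5, "none": 0,
    }
    truth = pd.DataFrame(
        {
            "tier": tiers,
            "direction": directions.astype(int),
            "channel": channels,
            "expected_recurrence": [expected_recurrence[t] for t in tiers],
        },
        index=feature_ids,
    )
    truth.index.name = "feature_id"
    table = FeatureTable(abundance, annotation, design)
    return table, truth


# ---------------------------------------------------------------------------
# Calibration layer
# ---------------------------------------------------------------------------


@dataclass
class CalibrationFixture:
    """Ground truth for synthetic calibration curves and QC injections.

    Noise on area ratios scales with concentration (constant relative
    error), the regime a 1/x^2 weighted fit is designed for.  ``bias``
    multiplies QC responses of selected analytes to simulate an analyte
    failing the accuracy gate.
    """

    n_analytes: int = 49
    levels: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0, 500.0)
    relative_noise: float = 0.02
    qc_nominal: float = 100.0
    n_qc: int = 6
    bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.levels) < 5:
            raise ValueError("at least 5 calibration levels are required")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("calibration levels must be strictly increasing")
        if self.relative_noise < 0:
            raise ValueError("noise scale must be nonnegative")

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(SPECIES_PANEL[: self.n_analytes])


def generate_calibration(
    fixture: CalibrationFixture | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate calibration points and QC injections per analyte.

    Returns ``(points, qc, truth)``: ``points`` has one row per (analyte,
    level) with the noisy area ratio; ``qc`` one row per (analyte, injection)
    at the QC nominal level; ``truth`` the true slope/intercept per analyte.
    """
    if seed is None:
        raise ValueError("an explicit seed is required (reproducibility)")
    fixture = fixture or CalibrationFixture()
    rng = np.random.default_rng(seed)
    conc = np.array(fixture.levels)

    rows, qc_rows, truth_rows = [], [], []
    for analyte in fixture.analytes:
        slope = rng.uniform(0.004, 0.02)
        intercept = rng.normal(0.0, 0.002)
        clean = slope * conc + intercept
        noisy = clean + rng.normal(0.0, 1.0, size=len(conc)) * fixture.relative_noise * slope * conc
        for c, y in zip(conc, noisy):
            rows.append({"analyte": analyte, "conc": c, "area_ratio": y})
        b = fixture.bias.get(analyte, 1.0)
        qc_clean = slope * fixture.qc_nominal + intercept
        for j in range(fixture.n_qc):
            y = b * (qc_clean + rng.normal(0.0, 1.0)
                     * fixture.relative_noise * slope * fixture.qc_nominal)
            qc_rows.append({"analyte": analyte, "injection": j + 1, "area_ratio": y})
        truth_rows.append({"analyte": analyte, "slope": slope, "intercept": intercept})
    points = pd.DataFrame(rows)
    qc = pd.DataFrame(qc_rows)
    truth = pd.DataFrame(truth_rows).set_index("analyte")
    return points, qc, truth
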