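import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lipomet.io import SampleDesign
from lipomet.targeted import (
    CalibrationCurve,
    VolumeConstants,
    back_calculate,
    compute_content,
    detection_filter,
    ffa_metrics,
    fit_calibration,
    parse_acyl,
    qc_evaluate,
    regime_summaries,
    summarize_metric,
    tukey_letters,
)


class TestCalibrationFit:
    @pytest.mark.parametrize("weighting", ["1/x", "1/x2", "none"])
    def test_noiseless_line_recovered_under_any_weighting(self, weighting):
        pts = [(x, 2.0 * x + 1.0) for x in (1.0, 2.0, 5.0, 10.0)]
        curve = fit_calibration(pts, weighting)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_inverse_x_fit_matches_hand_solved_normal_equations(self):
        # w_i = 1/x_i for points (1,1),(2,3),(4,5):
        #   [sum w x^2, sum w x; sum w x, sum w] [a; b] = [sum w x y; sum w y]
        pts = [(1.0, 1.0), (2.0, 3.0), (4.0, 5.0)]
        w = np.array([1.0, 0.5, 0.25])
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 5.0])
        A = np.array([[np.sum(w * x * x), np.sum(w * x)], [np.sum(w * x), np.sum(w)]])
        a, b = np.linalg.solve(A, np.array([np.sum(w * x * y), np.sum(w * y)]))
        curve = fit_calibration(pts, "1/x")
        assert curve.slope == pytest.approx(a, abs=1e-12)
        assert curve.intercept == pytest.approx(b, abs=1e-12)

    def test_unit_weights_equal_ordinary_least_squares(self):
        rng = np.random.default_rng(4)
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
        y = 0.8 * x + 0.3 + rng.normal(0, 0.5, len(x))
        curve = fit_calibration(list(zip(x, y)), "none")
        slope, intercept = np.polyfit(x, y, 1)
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_inverse_x2_weighting_shrinks_low_end_relative_residuals(self):
        # heteroscedastic noise proportional to concentration
        rng = np.random.default_rng(7)
        x = np.array([1.0, 2.0, 5.0, 10.0, 50.0, 100.0, 500.0])
        resid_lo = {}
        for weighting in ("1/x", "1/x2"):
            rel = []
            for _ in range(200):
                y = 0.01 * x * (1 + rng.normal(0, 0.08, len(x))) + 0.001
                c = fit_calibration(list(zip(x, y)), weighting)
                pred = c.slope * x + c.intercept
                rel.append(np.abs((y - pred) / y)[:2].mean())
            resid_lo[weighting] = np.mean(rel)
        assert resid_lo["1/x2"] < resid_lo["1/x"]

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_calibration([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])


class TestBackCalculation:
    curve = CalibrationCurve("x", slope=2.0, intercept=0.0, weighting="1/x",
                             r_squared=1.0, linear_range=(1, 100))

    def test_ratio_equal_to_intercept_maps_to_zero(self):
        c = CalibrationCurve("x", 2.0, 0.7, "1/x", 1.0, (1, 100))
        conc, below = back_calculate(0.7, c)
        assert conc[0] == 0.0 and not below[0]

    def test_simple_inversion(self):
        conc, below = back_calculate(10.0, self.curve)
        assert conc[0] == pytest.approx(5.0)
        assert not below.any()

    def test_ratio_below_intercept_clamped_and_flagged(self):
        c = CalibrationCurve("x", 2.0, 1.0, "1/x", 1.0, (1, 100))
        conc, below = back_calculate(0.5, c)
        assert conc[0] == 0.0 and below[0]

    def test_zero_slope_is_an_error(self):
        c = CalibrationCurve("x", 0.0, 0.0, "1/x", 1.0, (1, 100))
        with pytest.raises(ZeroDivisionError):
            back_calculate(1.0, c)


class TestContentFormula:
    def test_reference_value(self):
        # 1000 * 0.16 * 1000 / (50 * 800) = 4.0 ng/mg
        assert compute_content(1000.0, 50.0) == pytest.approx(4.0)

    def test_zero_concentration_gives_zero(self):
        assert compute_content(0.0, 50.0) == 0.0

    @given(
        cs=st.floats(0.01, 1e5),
        mass=st.floats(0.1, 1e3),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_and_mass_inverse(self, cs, mass, scale):
        base = compute_content(cs, mass)
        assert compute_content(scale * cs, mass) == pytest.approx(scale * base, rel=1e-9)
        assert compute_content(cs, scale * mass) == pytest.approx(base / scale, rel=1e-9)
        vols = VolumeConstants(V1=0.16 * scale, V2=1000.0, V3=800.0)
        assert compute_content(cs, mass, vols) == pytest.approx(scale * base, rel=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_content(1.0, 0.0)


class TestQcGate:
    def test_exact_measurements_pass(self):
        out = qc_evaluate([100.0, 100.0, 100.0], 100.0)
        assert out == {"accuracy": 1.0, "rsd": 0.0, "pass": True}

    @pytest.mark.parametrize(
        "factor, expect",
        [(0.79, False), (0.80, True), (1.20, True), (1.21, False)],
    )
    def test_accuracy_bounds_inclusive(self, factor, expect):
        out = qc_evaluate([100.0 * factor] * 3, 100.0)
        assert out["pass"] is expect

    def test_rsd_bound_inclusive(self):
        # mean 100, sd exactly 20 -> RSD 0.20 passes; above fails
        x = np.array([80.0, 120.0])
        out = qc_evaluate(x, 100.0)
        assert out["rsd"] == pytest.approx(np.std(x, ddof=1) / 100.0)
        assert qc_evaluate([70.0, 130.0], 100.0)["pass"] is False


class TestDetectionAndMetrics:
    def test_detection_requires_one_positive_sample(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.1], [1.0, 2.0]],
            index=["FFA 18:0", "FFA 18:1", "FFA 18:2"],
            columns=["A1", "A2"],
        )
        det = detection_filter(df)
        assert list(det) == [False, True, True]
        assert not detection_filter(df * 0).any()

    def test_parse_acyl(self):
        assert parse_acyl("FFA 18:1") == (18, 1)
        with pytest.raises(ValueError):
            parse_acyl("oleic acid")

    def test_single_mufa_species(self):
        df = pd.DataFrame([[5.0]], index=["FFA 18:1"], columns=["A1"])
        m = ffa_metrics(df)
        assert m.loc["A1", "MUFA_pct"] == pytest.approx(100.0)
        assert np.isnan(m.loc["A1", "OL_ratio"])  # linoleic absent

    def test_equal_saturation_classes_split_evenly(self):
        df = pd.DataFrame(
            [[3.0], [3.0], [3.0]],
            index=["FFA 18:0", "FFA 18:1", "FFA 18:2"],
            columns=["A1"],
        )
        m = ffa_metrics(df)
        for col in ("SFA_pct", "MUFA_pct", "PUFA_pct"):
            assert m.loc["A1", col] == pytest.approx(100 / 3)
        assert m.loc["A1", "OL_ratio"] == pytest.approx(1.0)

    def test_saturation_percentages_sum_to_100(self, targeted):
        table, _ = targeted
        m = ffa_metrics(table)
        total_pct = m[["SFA_pct", "MUFA_pct", "PUFA_pct"]].sum(axis=1)
        assert np.allclose(total_pct, 100.0, atol=1e-9)

    def test_unsaturated_fraction_shifts_from_a_to_d(self, targeted, design):
        table, _ = targeted
        m = ffa_metrics(table)
        unsat = (m["MUFA_pct"] + m["PUFA_pct"]).groupby(design.regime_of()).mean()
        assert unsat["A"] == pytest.approx(63.29, abs=1.0)
        assert unsat["D"] == pytest.approx(79.87, abs=1.0)


def _letters_consistent(letters: dict, sig: np.ndarray, labels: list) -> bool:
    """Two groups share a letter iff they are not significantly different."""
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            share = bool(set(letters[a]) & set(letters[b]))
            if share == bool(sig[i, j]):
                return False
    return True


class TestRegimeStatistics:
    def test_identical_samples_share_one_letter(self, design):
        per_sample = pd.Series(5.0, index=list(design.sample_ids))
        s = summarize_metric(per_sample, design)
        assert s.anova_p == pytest.approx(1.0)
        assert len(set(s.letters.values())) == 1

    def test_single_outlying_regime_gets_unique_letter(self, design):
        rng = np.random.default_rng(0)
        vals = {s: rng.normal(0.0, 1e-3) for s in design.sample_ids}
        for s in design.samples_of("D"):
            vals[s] = 100.0 + rng.normal(0.0, 1e-3)
        s = summarize_metric(pd.Series(vals), design)
        d = set(s.letters["D"])
        for r in "ABC":
            assert not d & set(s.letters[r])
        assert s.letters["A"] == s.letters["B"] == s.letters["C"]

    def test_default_targeted_data_separates_regime_d(self, targeted, design):
        table, _ = targeted
        out = regime_summaries(table, design, per_species=False)["total"]
        assert out.anova_p < 1e-6
        d = set(out.letters["D"])
        for r in "ABC":
            assert not d & set(out.letters[r])
        assert out.stats.loc["D", "mean"] > out.stats.loc["C", "mean"]

    def test_sem_definition(self, design):
        rng = np.random.default_rng(1)
        per_sample = pd.Series(rng.normal(10, 2, 12), index=list(design.sample_ids))
        s = summarize_metric(per_sample, design)
        g = per_sample[design.samples_of("B")]
        assert s.stats.loc["B", "sem"] == pytest.approx(g.std(ddof=1) / np.sqrt(3))

    @pytest.mark.parametrize("seed", range(8))
    def test_letters_match_bruteforce_tukey_decisions(self, design, seed):
        """Compact letters agree with the full pairwise decision matrix from
        an independent Tukey HSD (scipy) on random data."""
        rng = np.random.default_rng(seed)
        shift = rng.choice([0.0, 1.0, 3.0, 10.0], size=4)
        vals = {}
        for k, r in enumerate("ABCD"):
            for s in design.samples_of(r):
                vals[s] = shift[k] + rng.normal(0, 1.0)
        per_sample = pd.Series(vals)
        summ = summarize_metric(per_sample, design)
        groups = [per_sample[design.samples_of(r)].to_numpy() for r in "ABCD"]
        oracle = sps.tukey_hsd(*groups)
        sig = oracle.pvalue < 0.05
        np.fill_diagonal(sig, False)
        assert np.allclose(summ.tukey_p.to_numpy(), oracle.pvalue, atol=1e-8)
        assert _letters_consistent(summ.letters, sig, list("ABCD"))

    def test_single_replicate_is_an_error(self):
        design = SampleDesign(("A1", "B1", "B2"), ("A", "B", "B"), (1, 1, 2))
        with pytest.raises(Exception, match="replicate"):
            summarize_metric(pd.Series([1.0, 2.0, 3.0], index=["A1", "B1", "B2"]), design)


class TestLetterDisplay:
    def test_arbitrary_decision_matrix_is_represented_exactly(self):
        # chain pattern: A~B, B~C significant only A-C
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 2] = sig[2, 0] = True
        letters = tukey_letters(sig, ["A", "B", "C"])
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])
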