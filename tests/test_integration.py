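from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lipomet.chemometrics import preprocess
from lipomet.integration import (
    bh_fdr,
    elasticnet_classify,
    signature_score,
    spearman_couple,
    spearman_permutation_p,
    superclass_enrichment,
)
from lipomet.io import SampleDesign
from lipomet.targeted import ffa_metrics


class TestSignatureScore:
    def test_single_member_equals_its_z_profile(self, untargeted):
        table, _ = untargeted
        mat = preprocess(table)
        feat = mat.feature_ids[0]
        sig = signature_score(mat, [feat])
        col = mat.values[:, 0]
        assert np.allclose(sig.scores.to_numpy(), col)

    def test_empty_member_set_is_an_error(self, untargeted):
        table, _ = untargeted
        mat = preprocess(table)
        with pytest.raises(ValueError, match="empty"):
            signature_score(mat, [])
        with pytest.raises(ValueError, match="absent"):
            signature_score(mat, ["no-such-feature"])

    def test_planted_core_signature_orders_regimes(self, untargeted):
        table, truth = untargeted
        mat = preprocess(table)
        up = truth.index[(truth["tier"] == "core_shared") & (truth["direction"] == 1)]
        sig = signature_score(mat, list(up), "core_up")
        means = sig.scores.groupby(table.design.regime_of()).mean()
        assert means["A"] < means["C"]
        assert means["A"] < means["D"]
        assert means["C"] == pytest.approx(means["D"], abs=0.5)


class TestSpearman:
    def test_monotone_pairs(self, design):
        x = pd.Series(np.arange(12.0), index=list(design.sample_ids))
        metrics = pd.DataFrame({"total": x**3})
        from lipomet.integration import SignatureScore

        out = spearman_couple(
            [SignatureScore("s", x)], metrics, metric_names=("total",),
            n_resamples=999, seed=0,
        )
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        metrics = pd.DataFrame({"total": -x})
        out = spearman_couple(
            [SignatureScore("s", x)], metrics, metric_names=("total",),
            n_resamples=999, seed=0,
        )
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_permutation_p_matches_independent_oracle(self):
        """Monte-Carlo permutation p agrees with a 1e5-draw oracle that
        recomputes Spearman's rho per permutation."""
        rng = np.random.default_rng(17)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(0, 0.8, 12)
        p_impl = spearman_permutation_p(x, y, n_resamples=100_000, seed=1)
        obs = abs(sps.spearmanr(x, y).statistic)
        oracle_rng = np.random.default_rng(99)
        count = 0
        n_oracle = 100_000
        yy = y.copy()
        for _ in range(n_oracle):
            oracle_rng.shuffle(yy)
            if abs(sps.spearmanr(x, yy).statistic) >= obs - 1e-12:
                count += 1
        p_oracle = (1 + count) / (1 + n_oracle)
        mc_sd = np.sqrt(p_oracle * (1 - p_oracle) / n_oracle)
        assert abs(p_impl - p_oracle) < 4 * mc_sd + 1e-4

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rho_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r0 = sps.spearmanr(x, y).statistic
        r1 = sps.spearmanr(np.exp(x), y**3 + 5 * y).statistic
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_constant_vector_is_flagged(self, design):
        from lipomet.integration import SignatureScore

        x = pd.Series(1.0, index=list(design.sample_ids))
        metrics = pd.DataFrame(
            {"total": np.arange(12.0)}, index=list(design.sample_ids)
        )
        out = spearman_couple(
            [SignatureScore("s", x)], metrics, metric_names=("total",),
            n_resamples=99, seed=0,
        )
        assert out.loc[0, "flag"] == "constant"
        assert np.isnan(out.loc[0, "rho"])


class TestBhFdr:
    def test_equal_p_values_unchanged(self):
        assert np.allclose(bh_fdr([0.05] * 4), 0.05)

    def test_stepup_hand_case(self):
        # ranks 1..4: p*m/j = .04,.04,.04,.04 after the step-up minimum
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_dominates_p(self, ps):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _fisher_enumeration_oracle(a, b, c, d):
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    r1, n1, n2 = a + b, a + c, b + d
    N = a + b + c + d
    denom = comb(N, r1)
    p_obs = Fraction(comb(n1, a) * comb(n2, b), denom)
    total = Fraction(0)
    for k in range(max(0, r1 - n2), min(r1, n1) + 1):
        pk = Fraction(comb(n1, k) * comb(n2, r1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestEnrichment:
    def _background(self, classes):
        ids = [f"m{i}" for i in range(len(classes))]
        ann = pd.DataFrame({"superclass": classes}, index=ids)
        return ids, ann

    def test_identical_proportions_give_or_one_p_one(self):
        ids, ann = self._background(["X", "Y"] * 10)
        tier = set(ids[:10])  # 5 X, 5 Y -> same proportion as background
        out = superclass_enrichment({"t": tier}, ann, set(ids))
        row = out[out["superclass"] == "X"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        ids, ann = self._background(["X"] * 8 + ["Y"] * 12)
        tier = set(ids[:6]) | set(ids[10:12])  # 6 X + 2 Y
        out = superclass_enrichment({"t": tier}, ann, set(ids))
        row = out[out["superclass"] == "X"].iloc[0]
        oracle = _fisher_enumeration_oracle(6, 2, 2, 10)
        assert row["p"] == pytest.approx(oracle, abs=1e-10)

    def test_zero_cell_uses_haldane_correction(self):
        ids, ann = self._background(["X"] * 5 + ["Y"] * 15)
        tier = set(ids[:5])  # all X, zero Y in tier
        out = superclass_enrichment({"t": tier}, ann, set(ids))
        row = out[out["superclass"] == "X"].iloc[0]
        assert np.isfinite(row["odds_ratio"])
        assert row["flag"] == "haldane"

    def test_tier_outside_background_rejected(self):
        ids, ann = self._background(["X"] * 4)
        with pytest.raises(ValueError, match="background"):
            superclass_enrichment({"t": {"stranger"}}, ann, set(ids))

    def test_q_values_are_within_tier_bh(self):
        ids, ann = self._background(["X"] * 6 + ["Y"] * 6 + ["Z"] * 8)
        out = superclass_enrichment({"t": set(ids[:6])}, ann, set(ids))
        assert np.allclose(
            out["q"].to_numpy(), bh_fdr(out["p"].to_numpy()), atol=1e-12
        )


class TestElasticNet:
    def test_planted_ffa_matrix_classifies_regimes(self, targeted, design):
        table, _ = targeted
        report = elasticnet_classify(table, design, n_repeats=5, seed=7)
        assert report.accuracy >= 0.9
        assert report.macro_f1 >= 0.9
        assert report.macro_auc >= 0.9
        # row-normalised confusion sums to 100
        assert np.allclose(report.confusion_percent.sum(axis=1), 100.0)

    def test_out_of_fold_bookkeeping_is_exhaustive(self, targeted, design):
        table, _ = targeted
        report = elasticnet_classify(table, design, n_repeats=3, seed=1)
        per_repeat = report.fold_assignments.groupby("repeat")["sample_id"].nunique()
        assert (per_repeat == 12).all()
        # no sample appears in two folds of the same repeat
        dup = report.fold_assignments.duplicated(["repeat", "sample_id"])
        assert not dup.any()

    def test_label_permutation_drops_accuracy_to_chance(self, targeted, design):
        table, _ = targeted
        rng = np.random.default_rng(5)
        accs = []
        for rep in range(20):
            perm = rng.permutation(design.n_samples)
            shuffled = SampleDesign(
                design.sample_ids,
                tuple(np.array(design.regimes)[perm]),
                design.replicates,
            )
            r = elasticnet_classify(table, shuffled, n_repeats=1, seed=rep)
            accs.append(r.accuracy)
        assert 0.10 <= np.mean(accs) <= 0.40  # 4-class chance is 0.25

    def test_fixed_seed_reproduces_report(self, targeted, design):
        table, _ = targeted
        r1 = elasticnet_classify(table, design, n_repeats=2, seed=3)
        r2 = elasticnet_classify(table, design, n_repeats=2, seed=3)
        assert r1.accuracy == r2.accuracy
        assert r1.confusion_counts.equals(r2.confusion_counts)
        assert r1.coefficient_ranking.equals(r2.coefficient_ranking)

    def test_thin_classes_rejected(self, targeted):
        table, _ = targeted
        thin = SampleDesign(
            tuple(table.columns[:8]),
            ("A", "A", "A", "B", "B", "B", "C", "C"),
            (1, 2, 3, 1, 2, 3, 1, 2),
        )
        with pytest.raises(ValueError, match="3 samples"):
            elasticnet_classify(table[list(thin.sample_ids)], thin)


class TestEndToEndCoupling:
    def test_pressure_signature_couples_to_ffa_axis(self, targeted, untargeted):
        """A signature built from D-responsive planted features correlates
        with total FFA (which peaks in regime D) after BH-FDR."""
        ffa, _ = targeted
        table, truth = untargeted
        mat = preprocess(table)
        up = truth.index[(truth["tier"] == "five_of_six") & (truth["direction"] == 1)]
        sig = signature_score(mat, list(up), "pressure_up")
        metrics = ffa_metrics(ffa)
        out = spearman_couple([sig], metrics, n_resamples=20_000, seed=2)
        row = out[out["metric"] == "total"].iloc[0]
        assert row["rho"] > 0.7
        assert row["q"] < 0.05
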