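import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alpinekin.stats import (
    classify_effect,
    cohens_d_mixed,
    contrasts_to_frame,
    estimated_marginal_means,
    fit_mixed,
    maybe_log_transform,
    tukey_contrasts,
)

DISC = ("SL", "GS", "SG", "DH")


def _table(rng, n_ids=8, n_cycles=6, disc_means=None, leg_effect=None,
           id_sd=0.0, noise_sd=4.0, interaction=None):
    """Balanced metrics-like table; every ID sees every cell."""
    disc_means = disc_means or {d: 30.0 for d in DISC}
    leg_effect = leg_effect or {"IL": 0.0, "OL": 0.0}
    interaction = interaction or {}
    rows = []
    for i in range(n_ids):
        u = rng.normal(0, id_sd)
        for d in DISC:
            for leg in ("IL", "OL"):
                for _ in range(n_cycles):
                    y = (disc_means[d] + leg_effect[leg]
                         + interaction.get((d, leg), 0.0) + u
                         + rng.normal(0, noise_sd))
                    rows.append({"ID": f"id{i}", "discipline": d, "leg": leg, "y": y})
    return pd.DataFrame(rows)


class TestFitMixed:
    def test_null_model_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        df = _table(rng, n_ids=25, n_cycles=10, noise_sd=1.0, id_sd=0.0)
        res = fit_mixed(df, "y", transform="none")
        # all non-intercept fixed effects ~ 0 within Monte-Carlo error
        fe = res.params.drop("Intercept")
        assert np.all(np.abs(fe) < 0.25)
        assert res.group_var < 0.05
        assert res.params["Intercept"] == pytest.approx(30.0, abs=0.2)

    def test_balanced_zero_id_variance_matches_ols(self):
        rng = np.random.default_rng(1)
        df = _table(rng, n_ids=6, n_cycles=4, id_sd=0.0,
                    disc_means={"SL": 10, "GS": 20, "SG": 28, "DH": 31})
        res = fit_mixed(df, "y", transform="none")
        # OLS oracle on the same design matrix
        import patsy

        y, X = patsy.dmatrices("y ~ C(discipline) * C(leg)", df, return_type="matrix")
        beta = np.linalg.lstsq(np.asarray(X), np.asarray(y).ravel(), rcond=None)[0]
        np.testing.assert_allclose(res.params.values, beta, atol=1e-6)

    def test_interaction_power(self):
        """Interaction of +15 points on OL between disciplines is detected."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(10):
            df = _table(
                rng, n_ids=20, n_cycles=20, id_sd=3.0, noise_sd=8.0,
                disc_means={"SL": 15, "GS": 25, "SG": 30, "DH": 30},
                interaction={("SG", "OL"): 15.0, ("DH", "OL"): 15.0},
            )
            res = fit_mixed(df, "y", transform="none")
            if res.term_pvalue("C(discipline):C(leg)") < 0.001:
                hits += 1
        assert hits >= 9

    def test_recovers_id_variance(self):
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(30):
            df = _table(rng, n_ids=10, n_cycles=10, id_sd=3.0, noise_sd=5.0)
            res = fit_mixed(df, "y", transform="none")
            ests.append(res.group_var)
        # unbiased within Monte-Carlo CI around the true variance 9
        assert np.mean(ests) == pytest.approx(9.0, abs=2.5)

    def test_reduced_formula(self):
        rng = np.random.default_rng(4)
        df = _table(rng, disc_means={"SL": 60, "GS": 64, "SG": 58, "DH": 57})
        res = fit_mixed(df, "y", formula="{y} ~ C(discipline)", transform="none")
        assert list(res.anova["term"]) == ["C(discipline)"]

    def test_too_few_groups_raises(self):
        df = pd.DataFrame({
            "ID": ["a"] * 5 + ["b"] * 5,
            "discipline": ["SL", "GS"] * 5,
            "leg": ["IL", "OL"] * 5,
            "y": np.arange(10.0),
        })
        with pytest.raises(ValueError, match="3 ID groups"):
            fit_mixed(df, "y")

    def test_single_level_factor_raises(self):
        rng = np.random.default_rng(5)
        df = _table(rng)
        df = df[df.discipline == "SL"]
        with pytest.raises(ValueError, match="2 levels"):
            fit_mixed(df, "y")

    def test_null_pvalues_roughly_uniform(self):
        """ANOVA p of a zero-effect term over null replicates vs U(0,1)."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            df = _table(rng, n_ids=10, n_cycles=3, id_sd=2.0, noise_sd=5.0)
            res = fit_mixed(df, "y", transform="none")
            pvals.append(res.term_pvalue("C(discipline)"))
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestMaybeLogTransform:
    def test_normal_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 5, 500)
        out, flag = maybe_log_transform(x)
        assert flag == "none"
        np.testing.assert_array_equal(out, x)

    def test_lognormal_transformed(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2.0, 1.0, 500)
        out, flag = maybe_log_transform(x)
        assert flag == "log"
        # transformed values pass the same normality check
        _, p = sps.shapiro(np.random.default_rng(0).choice(out, 400, replace=False))
        assert p > 0.01

    def test_constant_untouched(self):
        out, flag = maybe_log_transform(np.full(100, 7.0))
        assert flag == "none"

    def test_nonpositive_blocked_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(1.0, 1.5, 500) - 1.0  # non-normal, some <= 0
        with pytest.warns(UserWarning):
            out, flag = maybe_log_transform(x)
        assert flag == "none"


class TestTukeyContrasts:
    def test_two_groups_matches_unadjusted_t(self):
        rng = np.random.default_rng(7)
        df = _table(rng, disc_means={"SL": 20, "GS": 24, "SG": 20, "DH": 24})
        df = df[df.discipline.isin(["SL", "GS"])]
        res = fit_mixed(df, "y", transform="none")
        cs = tukey_contrasts(res, "discipline")
        assert len(cs) == 1
        c = cs[0]
        t = abs(c.estimate) / c.se
        p_t = 2 * sps.t.sf(t, res.df_resid)
        assert c.p_adj == pytest.approx(p_t, rel=1e-3)

    def test_known_ordering_recovered(self):
        rng = np.random.default_rng(8)
        df = _table(rng, n_ids=10, n_cycles=8, noise_sd=3.0,
                    disc_means={"SL": 10, "GS": 20, "SG": 30, "DH": 30})
        res = fit_mixed(df, "y", transform="none")
        cs = {(c.level_a, c.level_b): c for c in tukey_contrasts(res, "discipline")}
        assert cs[("GS", "SL")].estimate > 0
        assert cs[("SG", "SL")].estimate > 0
        assert cs[("GS", "SG")].estimate < 0

    def test_familywise_error_controlled(self):
        """k=4 equal means: probability of any adjusted p < .05 stays near .05."""
        rng = np.random.default_rng(9)
        n_rep, fw = 150, 0
        for _ in range(n_rep):
            df = _table(rng, n_ids=8, n_cycles=2, id_sd=1.0, noise_sd=5.0)
            res = fit_mixed(df, "y", transform="none")
            cs = tukey_contrasts(res, "discipline")
            if any(c.p_adj < 0.05 for c in cs):
                fw += 1
        assert fw / n_rep <= 0.08

    def test_by_slices_form_families(self):
        rng = np.random.default_rng(10)
        df = _table(rng)
        res = fit_mixed(df, "y", transform="none")
        cs = tukey_contrasts(res, "discipline", by="leg")
        fams = {c.family for c in cs}
        assert fams == {"discipline|leg=IL", "discipline|leg=OL"}
        assert len(cs) == 12  # 6 pairs per leg

    def test_contrast_frame(self):
        rng = np.random.default_rng(11)
        df = _table(rng)
        res = fit_mixed(df, "y", transform="none")
        frame = contrasts_to_frame(tukey_contrasts(res, "leg"))
        assert {"family", "estimate", "p_adj", "cohens_d", "magnitude"} <= set(frame.columns)


class TestCohensD:
    def test_zero_difference(self):
        assert cohens_d_mixed(0.0, 4.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert cohens_d_mixed(8.0, 9.0, 55.0) == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            cohens_d_mixed(1.0, 0.0, 0.0)

    def test_matches_classic_d_when_id_variance_zero(self):
        rng = np.random.default_rng(12)
        df = _table(rng, n_ids=12, n_cycles=10, id_sd=0.0, noise_sd=6.0,
                    disc_means={"SL": 20, "GS": 26, "SG": 20, "DH": 20})
        df = df[df.discipline.isin(["SL", "GS"])]
        res = fit_mixed(df, "y", transform="none")
        c = tukey_contrasts(res, "discipline")[0]
        a = df[df.discipline == "SL"]["y"].to_numpy()
        b = df[df.discipline == "GS"]["y"].to_numpy()
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        classic = abs(a.mean() - b.mean()) / pooled
        assert c.cohens_d == pytest.approx(classic, rel=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        df = _table(rng, disc_means={"SL": 10, "GS": 18, "SG": 14, "DH": 12},
                    id_sd=2.0)
        res1 = fit_mixed(df, "y", transform="none")
        d1 = [c.cohens_d for c in tukey_contrasts(res1, "discipline")]
        df2 = df.copy()
        df2["y"] = 3.7 * df2["y"] - 100.0
        res2 = fit_mixed(df2, "y", transform="none")
        d2 = [c.cohens_d for c in tukey_contrasts(res2, "discipline")]
        np.testing.assert_allclose(d1, d2, rtol=1e-4)


class TestClassifyEffect:
    @pytest.mark.parametrize("d,label", [
        (0.0, "trivial"),
        (0.19, "trivial"),
        (0.20, "small"),
        (0.49, "small"),
        (0.50, "medium"),
        (0.79, "medium"),
        (0.80, "large"),
        (1.16, "large"),
    ])
    def test_thresholds(self, d, label):
        assert classify_effect(d) == label

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_effect(-0.1)


class TestEstimatedMarginalMeans:
    def test_recovers_cell_means_balanced(self):
        rng = np.random.default_rng(14)
        means = {"SL": 12.0, "GS": 22.0, "SG": 30.0, "DH": 31.0}
        df = _table(rng, n_ids=12, n_cycles=8, noise_sd=2.0, disc_means=means)
        res = fit_mixed(df, "y", transform="none")
        emms = estimated_marginal_means(res, "discipline")
        for _, row in emms.iterrows():
            assert row["emm"] == pytest.approx(means[row["level"]], abs=0.5)
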