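"""Repeated-measures ANOVA, Holm post-hocs, bootstrap correlations."""

import numpy as np
import pandas as pd
import pytest

from thetaconn import bootstrap_correlation, posthoc, rm_anova


def _long(values, subjects=None):
    """values: (n_subjects, n_sessions) -> tidy frame."""
    values = np.asarray(values, dtype=float)
    n_s, n_l = values.shape
    subjects = subjects or range(n_s)
    rows = [
        {"subject": s, "session": f"S{j}", "value": values[i, j]}
        for i, s in enumerate(subjects)
        for j in range(n_l)
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_location_invariance(self, rng):
        vals = rng.random((8, 3))
        f0 = rm_anova(_long(vals)).effect("session")["F"]
        f1 = rm_anova(_long(vals + 123.4)).effect("session")["F"]
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_toy_table_matches_hand_computed_sums_of_squares(self):
        """4 subjects x 3 sessions against an explicit one-way RM decomposition."""
        vals = np.array(
            [[1.0, 2.0, 4.0], [2.0, 3.0, 3.0], [0.0, 2.0, 5.0], [1.0, 1.0, 4.0]]
        )
        n, k = vals.shape
        grand = vals.mean()
        ss_sessions = n * ((vals.mean(axis=0) - grand) ** 2).sum()
        ss_subjects = k * ((vals.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((vals - grand) ** 2).sum()
        ss_error = ss_total - ss_sessions - ss_subjects
        f_expected = (ss_sessions / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
        res = rm_anova(_long(vals)).effect("session")
        assert res["F"] == pytest.approx(f_expected, rel=1e-9)
        assert (res["df1"], res["df2"]) == (k - 1, (k - 1) * (n - 1))

    def test_null_p_values_roughly_uniform(self):
        """Pure-noise sessions: the session p-value is uniform over seeds."""
        from scipy.stats import kstest

        ps = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            res = rm_anova(_long(rng.standard_normal((8, 3))))
            ps.append(res.effect("session")["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_listwise_drop_of_incomplete_subjects(self):
        df = _long(np.random.default_rng(2).random((4, 3)))
        df.loc[(df.subject == 0) & (df.session == "S2"), "value"] = np.nan
        res = rm_anova(df)
        assert res.n_subjects == 3
        assert res.dropped_subjects == [0]

    def test_mixed_design_needs_two_per_group(self):
        df = _long(np.random.default_rng(0).random((3, 3)))
        df["hand"] = ["L"] * 3 + ["R"] * 6
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(df, between="hand")

    def test_mixed_design_reports_all_effects(self):
        rng = np.random.default_rng(1)
        df = _long(rng.random((8, 3)))
        df["hand"] = np.where(df.subject < 4, "L", "R")
        res = rm_anova(df, between="hand")
        effects = set(res.table["effect"].str.lower())
        assert {"session", "hand", "interaction"} <= effects


class TestPosthoc:
    def test_identical_samples_give_unit_p(self):
        vals = np.tile([[1.0, 1.0]], (6, 1))
        out = posthoc(_long(vals), [("S0", "S1")])
        assert out.loc[0, "statistic"] == 0.0
        assert out.loc[0, "p_raw"] == 1.0

    def test_holm_adjustment_matches_direct_recursion(self, rng):
        vals = rng.standard_normal((10, 3)) + np.array([0.0, 0.4, 1.0])
        out = posthoc(_long(vals), [("S0", "S1"), ("S0", "S2"), ("S1", "S2")])
        raw = out["p_raw"].to_numpy()
        order = np.argsort(raw)
        m = len(raw)
        stepped = np.maximum.accumulate([(m - k) * raw[order[k]] for k in range(m)])
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(out["p_holm"], expected, rtol=1e-12)

    def test_known_holm_sequence(self):
        """Raw p (0.01, 0.02, 0.04) Holm-adjusts to (0.03, 0.04, 0.04)."""
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_wilcoxon_fallback_for_non_normal_differences(self, rng):
        base = rng.standard_normal(40)
        heavy = base + np.sign(rng.standard_normal(40)) * rng.exponential(3.0, 40) ** 2
        df = _long(np.column_stack([heavy, base]))
        out = posthoc(df, [("S0", "S1")])
        assert out.loc[0, "test"] == "wilcoxon"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            posthoc(_long(np.ones((2, 2))), [("S0", "S1")])

    def test_missing_level_rejected(self):
        df = _long(np.ones((4, 2)))
        with pytest.raises(ValueError, match="no observations"):
            posthoc(df, [("S0", "S9")])


class TestBootstrapCorrelation:
    def test_perfect_positive(self, rng):
        x = rng.standard_normal(12)
        res = bootstrap_correlation(x, 2 * x + 1, n_boot=500, rng=0)
        assert res.rho == pytest.approx(1.0)
        assert res.ci == (1.0, 1.0)
        assert res.p < 0.05

    def test_perfect_negative(self, rng):
        x = rng.standard_normal(12)
        res = bootstrap_correlation(x, -x, n_boot=500, rng=0)
        assert res.rho == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bootstrap_correlation(np.ones(10), np.arange(10.0), n_boot=100)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            bootstrap_correlation(np.arange(4.0), np.arange(4.0), n_boot=100)

    def test_pearson_flag(self, rng):
        x = rng.standard_normal(20)
        y = x + 0.3 * rng.standard_normal(20)
        res = bootstrap_correlation(x, y, n_boot=500, rng=1, method="pearson")
        assert res.method == "pearson"
        assert res.rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_null_p_uniformity(self):
        """Independent inputs: permutation p-values are uniform over seeds."""
        from scipy.stats import kstest

        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = bootstrap_correlation(
                rng.standard_normal(12), rng.standard_normal(12), n_boot=400, rng=seed
            )
            ps.append(res.p)
        assert kstest(ps, "uniform").pvalue > 0.01
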