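"""Repeated-measures ANOVA, GG epsilon, Bonferroni and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from onhlab.stats import (
    bonferroni_adjust,
    gg_epsilon,
    group_summary,
    pairwise_posthoc,
    rm_anova,
    rm_anova_array,
)
from onhlab.synthetic import StudyDesign, generate_study_dataset


def brute_force_oneway_f(y: np.ndarray) -> float:
    """Explicit-loop SS partition for a one-way within-subject design."""
    n, k = y.shape
    gm = y.mean()
    ss_a = sum(n * (y[:, j].mean() - gm) ** 2 for j in range(k))
    ss_s = sum(k * (y[i, :].mean() - gm) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_a - ss_s
    return (ss_a / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


def brute_force_epsilon(y: np.ndarray) -> float:
    """GG epsilon from the covariance matrix written out element by element."""
    n, k = y.shape
    s = np.cov(y, rowvar=False)
    sbar = s.mean()
    row = s.mean(axis=1)
    num = (k * (np.trace(s) / k - sbar)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row**2).sum() + k * k * sbar**2
    )
    return num / den


class TestEpsilon:
    def test_compound_symmetry_gives_unity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 2, (5000, 1)) + rng.normal(0, 1, (5000, 4))
        assert gg_epsilon(y) == pytest.approx(1.0, abs=0.01)

    def test_maximal_nonsphericity_hits_lower_bound(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (12, 1))
        y = np.hstack([base, -base, np.zeros((12, 1))])
        y += 1e-4 * rng.normal(size=y.shape)
        assert gg_epsilon(y) == pytest.approx(0.5, abs=0.01)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(size=(6, 4)) * rng.uniform(0.5, 2.0, 4)
            assert gg_epsilon(y) == pytest.approx(
                np.clip(brute_force_epsilon(y), 1 / 3, 1.0), rel=1e-10
            )

    @given(st.integers(0, 10_000))
    def test_bounds_hold_for_random_data(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        y = rng.normal(size=(int(rng.integers(3, 9)), k))
        eps = gg_epsilon(y)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((1, 3)))


class TestRmAnova:
    def test_oneway_equals_brute_force_on_50_datasets(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
            f_mine = rm_anova_array(y)[0].f_value
            assert abs(f_mine - brute_force_oneway_f(y)) / brute_force_oneway_f(y) < 1e-8

    def test_three_way_against_pingouin_two_way_margins(self):
        """Two-way marginals of the SS partition agree with pingouin."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        y = rng.normal(size=(8, 3, 2)) + rng.normal(size=(8, 1, 1))
        rows = [
            dict(subject=s, A=f"a{a}", B=f"b{b}", value=y[s, a, b])
            for s in range(8)
            for a in range(3)
            for b in range(2)
        ]
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "value", ["A", "B"]).set_index("effect")
        theirs = pg.rm_anova(data=df, dv="value", within=["A", "B"], subject="subject",
                             detailed=True).set_index("Source")
        for eff, src in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
            assert mine.loc[eff, "f_value"] == pytest.approx(theirs.loc[src, "F"], rel=1e-6)
            assert mine.loc[eff, "epsilon"] == pytest.approx(theirs.loc[src, "eps"], rel=1e-6)
            assert mine.loc[eff, "p_uncorrected"] == pytest.approx(
                theirs.loc[src, "p_unc"], rel=1e-6
            )

    def test_gg_correction_is_conservative_where_it_matters(self):
        # shrinking both dfs by epsilon inflates small p values (the
        # rejection regime); near F ~ 1 the ordering can flip, so the
        # conservativeness guarantee is asserted for p_unc <= 0.10
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            y = rng.normal(size=(6, 4)) * rng.uniform(0.3, 3.0, 4)
            y[:, 0] += rng.uniform(0.0, 2.0)  # sprinkle real effects in
            eff = rm_anova_array(y, gg_rule="always")[0]
            assert eff.df_corrected == pytest.approx(eff.df * eff.epsilon)
            if eff.p_uncorrected <= 0.10:
                assert eff.p_value >= eff.p_uncorrected - 1e-12
                checked += 1

    def test_null_type_one_error_calibrated(self):
        """Main-effect rejection rates under a pure-null 3x3x2 design, 1000 reps."""
        rng = np.random.default_rng(42)
        reps = 1000
        rej = np.zeros(3)
        for _ in range(reps):
            y = rng.normal(size=(6, 3, 3, 2)) + rng.normal(size=(6, 1, 1, 1))
            effs = rm_anova_array(y)
            rej += [effs[i].p_value < 0.05 for i in range(3)]
        for rate in rej / reps:
            assert 0.03 <= rate <= 0.07

    def test_incomplete_design_lists_missing_cells(self):
        df = pd.DataFrame(
            dict(subject=["s1", "s1", "s2"], w=[1, 2, 1], value=[1.0, 2.0, 3.0])
        )
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df, "value", ["w"])

    def test_constant_data_is_degenerate(self):
        y = np.ones((4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova_array(y)

    def test_detects_programmed_week_effect_with_high_power(self):
        """The default study's loop-on depression doubling is detected >=80%."""
        hits = 0
        reps = 200
        for s in range(reps):
            ds = generate_study_dataset(StudyDesign(seed=s))
            t = ds.endpoints
            dep = t[t.endpoint == "onh_depression_um"]
            res = rm_anova(dep, "value", ["week", "eye", "procedure"])
            hits += res.set_index("effect").loc["week", "p_value"] < 0.05
        assert hits / reps >= 0.80


class TestBonferroni:
    def test_capping_and_arithmetic(self):
        assert bonferroni_adjust([0.40], 3)[0] == 1.00
        assert bonferroni_adjust([0.004], 9)[0] == pytest.approx(0.036)
        assert bonferroni_adjust([0.2], 1)[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    def test_monotone_and_order_preserving(self, ps):
        adj = bonferroni_adjust(ps, len(ps))
        order0 = np.argsort(ps, kind="stable")
        assert np.all(np.asarray(ps) <= adj + 1e-12)
        assert np.all(np.diff(np.asarray(adj)[order0]) >= -1e-12)


class TestSummariesAndPosthoc:
    def test_hand_computed_cell(self):
        df = pd.DataFrame(dict(g=["a"] * 3, value=[10.0, 12.0, 14.0]))
        s = group_summary(df, ["g"]).iloc[0]
        assert s["mean"] == 12.0 and s["sd"] == 2.0
        assert s["se"] == pytest.approx(2.0 / np.sqrt(3))

    def test_single_value_flagged(self):
        df = pd.DataFrame(dict(g=["a"], value=[5.0]))
        s = group_summary(df, ["g"]).iloc[0]
        assert s["mean"] == 5.0 and np.isnan(s["sd"]) and s["flag"]

    def test_study_cell_mean_recovered_across_seeds(self):
        means = []
        for s in range(30):
            ds = generate_study_dataset(StudyDesign(seed=s))
            t = ds.endpoints
            cell = t[
                (t.endpoint == "onh_depression_um")
                & (t.eye == "treated")
                & (t.procedure == "loop")
                & (t.week == 1)
            ]
            means.append(group_summary(cell, ["week"]).iloc[0]["mean"])
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 89.3) < 3 * se

    def test_posthoc_bonferroni_family(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            [
                dict(subject=f"s{i}", w=w, value=rng.normal(w * 2.0, 1.0))
                for i in range(6)
                for w in (1, 5, 9)
            ]
        )
        out = pairwise_posthoc(df, "value", "w")
        assert len(out) == 3
        assert np.all(out.p_bonferroni <= 1.0)
        assert np.allclose(
            out.p_bonferroni, np.minimum(out.p_uncorrected * 3, 1.0)
        )
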