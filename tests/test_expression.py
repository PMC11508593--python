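import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from refstab import expression
from refstab.errors import DataError, DesignError
from refstab.expression import (
    assumption_checks,
    ddct_fold_change,
    delta_ct,
    fold_changes,
    pairwise_contrasts,
    quartile_outlier_filter,
    sidak_posthoc,
    two_way_anova,
)


@pytest.fixture
def cq_values():
    return pd.DataFrame(
        {"T": [25.0, 26.0, 24.0], "R1": [20.0, 20.0, 20.0], "R2": [22.0, 22.0, 22.0]},
        index=["s1", "s2", "s3"],
    )


class TestDeltaCt:
    def test_single_reference(self, cq_values):
        d = delta_ct(cq_values, "T", ["R1"])
        assert d["s1"] == 5.0

    def test_multi_reference_arithmetic_mean(self, cq_values):
        d = delta_ct(cq_values, "T", ["R1", "R2"])
        assert d["s2"] == 26.0 - 21.0

    def test_target_in_refs_refused(self, cq_values):
        with pytest.raises(DesignError, match="references"):
            delta_ct(cq_values, "T", ["T", "R1"])

    @given(offset=st.floats(-3, 3))
    def test_loading_offset_invariance(self, cq_values, offset):
        shifted = cq_values.copy()
        shifted.loc["s1"] = shifted.loc["s1"] + offset
        base = delta_ct(cq_values, "T", ["R1", "R2"])
        after = delta_ct(shifted, "T", ["R1", "R2"])
        assert after["s1"] == pytest.approx(base["s1"], abs=1e-9)


class TestFoldChange:
    def test_calibrator_mean_sample_has_fold_one(self):
        d = pd.Series({"s1": 6.0, "s2": 6.0})
        out = ddct_fold_change(d, ["s1", "s2"])
        assert out["fold"].tolist() == [1.0, 1.0]

    def test_lower_dct_doubles(self):
        out = ddct_fold_change(pd.Series({"a": 5.0, "c": 6.0}), ["c"])
        assert out.at["a", "fold"] == 2.0

    def test_higher_dct_quarters(self):
        out = ddct_fold_change(pd.Series({"a": 8.0, "c": 6.0}), ["c"])
        assert out.at["a", "fold"] == 0.25

    def test_disjoint_calibrator_refused(self):
        with pytest.raises(DataError, match="disjoint"):
            ddct_fold_change(pd.Series({"a": 5.0}), ["zz"])

    def test_calibrator_geometric_mean_fold_is_one(self):
        rng = np.random.default_rng(0)
        d = pd.Series(rng.normal(5, 1, 10), index=[f"s{i}" for i in range(10)])
        out = ddct_fold_change(d, list(d.index[:4]))
        cal_folds = out.loc[d.index[:4], "fold"]
        assert sps.gmean(cal_folds) == pytest.approx(1.0, abs=1e-12)

    @given(c=st.floats(0.25, 4.0))
    def test_equivariance_under_true_expression_scaling(self, c):
        """Scaling a group's expression by c scales its geometric-mean fold by c."""
        d = pd.Series({"cal1": 5.0, "cal2": 5.5, "t1": 4.0, "t2": 4.5})
        shifted = d.copy()
        shifted[["t1", "t2"]] -= np.log2(c)  # c-fold more template
        base = ddct_fold_change(d, ["cal1", "cal2"])
        after = ddct_fold_change(shifted, ["cal1", "cal2"])
        ratio = sps.gmean(after.loc[["t1", "t2"], "fold"]) / sps.gmean(
            base.loc[["t1", "t2"], "fold"]
        )
        assert ratio == pytest.approx(c, rel=1e-9)


class TestQuartileFilter:
    def test_single_high_outlier_flagged(self):
        res = quartile_outlier_filter(pd.Series([1.0, 1.1, 1.2, 1.3, 5.0]))
        assert res.fences == (pytest.approx(0.8), pytest.approx(1.6))
        assert res.flags.tolist() == [False, False, False, False, True]
        assert res.values.tolist() == [1.0, 1.1, 1.2, 1.3]

    def test_clean_symmetric_data_untouched(self):
        res = quartile_outlier_filter(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert not res.flags.any()

    def test_identical_values_not_flagged(self):
        res = quartile_outlier_filter(pd.Series([2.0] * 6))
        assert not res.flags.any()

    def test_small_cell_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="too few"):
            res = quartile_outlier_filter(pd.Series([1.0, 9.0, 2.0]))
        assert not res.flags.any() and res.fences is None


def _anova_oracle(df: pd.DataFrame, value: str, fa: str, fb: str) -> dict[str, tuple]:
    """Type-III two-way ANOVA by explicit design-matrix least squares.

    Sum-to-zero coding; each effect is tested by comparing the full model's
    residual SS with the model that drops that effect's columns while
    keeping all others.
    """
    a_levels = sorted(df[fa].unique())
    b_levels = sorted(df[fb].unique())

    def code(levels, values):
        # sum coding: last level = -1 on every indicator
        cols = []
        for lv in levels[:-1]:
            col = np.where(values == lv, 1.0, np.where(values == levels[-1], -1.0, 0.0))
            cols.append(col)
        return np.column_stack(cols)

    y = df[value].to_numpy(float)
    xa = code(a_levels, df[fa].to_numpy())
    xb = code(b_levels, df[fb].to_numpy())
    xab = np.column_stack(
        [xa[:, i] * xb[:, j] for i, j in itertools.product(range(xa.shape[1]), range(xb.shape[1]))]
    )
    intercept = np.ones((len(df), 1))

    def ssr(*blocks):
        X = np.column_stack(blocks)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    sse_full = ssr(intercept, xa, xb, xab)
    df_resid = len(df) - (1 + xa.shape[1] + xb.shape[1] + xab.shape[1])
    out = {}
    for name, dropped, kept in [
        (fa, xa, (intercept, xb, xab)),
        (fb, xb, (intercept, xa, xab)),
        (f"{fa}:{fb}", xab, (intercept, xa, xb)),
    ]:
        ss = ssr(*kept) - sse_full
        dof = dropped.shape[1]
        f = (ss / dof) / (sse_full / df_resid)
        p = sps.f.sf(f, dof, df_resid)
        out[name] = (ss, dof, f, p)
    out["residual"] = (sse_full, df_resid, np.nan, np.nan)
    return out


def _random_unbalanced(rng, with_effects=False):
    rows = []
    for g in ("intact", "control", "FS"):
        for a in ("P14", "P21", "P50"):
            n = rng.integers(3, 8)
            mu = 0.0
            if with_effects:
                mu = {"intact": 0, "control": 0.3, "FS": 0.8}[g] + {"P14": 0, "P21": -0.2, "P50": 0.5}[a]
            for _ in range(n):
                rows.append({"group": g, "age": a, "fold": mu + rng.normal()})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_least_squares_oracle_unbalanced(self):
        rng = np.random.default_rng(123)
        for trial in range(5):
            df = _random_unbalanced(rng, with_effects=(trial % 2 == 0))
            got = two_way_anova(df).set_index("effect")
            want = _anova_oracle(df, "fold", "group", "age")
            for effect in ("group", "age", "group:age"):
                ss, dof, f, p = want[effect]
                assert got.at[effect, "sum_sq"] == pytest.approx(ss, abs=1e-8)
                assert got.at[effect, "df"] == dof
                assert got.at[effect, "F"] == pytest.approx(f, abs=1e-8)
                assert got.at[effect, "p"] == pytest.approx(p, abs=1e-8)

    def test_additive_balanced_design_has_zero_interaction(self):
        rows = []
        for g, geff in (("intact", 0.0), ("FS", 1.0)):
            for a, aeff in (("P14", 0.0), ("P50", 0.5)):
                for r in range(2):
                    rows.append({"group": g, "age": a, "fold": geff + aeff + 0.1 * r})
        got = two_way_anova(pd.DataFrame(rows)).set_index("effect")
        assert got.at["group:age", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_factor_refused(self):
        df = pd.DataFrame(
            {"group": ["intact"] * 6, "age": ["P14", "P21", "P50"] * 2, "fold": np.arange(6.0)}
        )
        with pytest.raises(DesignError, match="group"):
            two_way_anova(df)

    def test_null_pvalues_are_uniform(self):
        """Under H0 the group-effect p-value is Uniform(0,1)."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(500):
            rows = [
                {"group": g, "age": a, "fold": rng.normal()}
                for g in ("intact", "control", "FS")
                for a in ("P14", "P21", "P50")
                for _ in range(4)
            ]
            res = two_way_anova(pd.DataFrame(rows)).set_index("effect")
            pvals.append(res.at["group", "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestSidak:
    def test_closed_form(self):
        assert sidak_posthoc(0.01, 3) == pytest.approx(0.029701, abs=1e-9)

    def test_endpoints(self):
        assert sidak_posthoc(0.0, 5) == 0.0
        assert sidak_posthoc(1.0, 5) == 1.0

    def test_single_comparison_is_identity(self):
        assert sidak_posthoc(0.37, 1) == pytest.approx(0.37)

    def test_invalid_p_refused(self):
        with pytest.raises(DataError):
            sidak_posthoc(1.5, 2)
        with pytest.raises(DesignError):
            sidak_posthoc(0.5, 0)

    @given(p=st.floats(0, 1), m=st.integers(1, 20))
    def test_adjustment_is_monotone_and_bounded(self, p, m):
        adj = sidak_posthoc(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-12


class TestContrasts:
    def test_family_size_reported_and_used(self):
        rng = np.random.default_rng(9)
        df = _random_unbalanced(rng)
        out = pairwise_contrasts(df)
        # 3 group pairs per age (x3) + 3 age pairs per group (x3)
        assert (out["m"] == 18).all() and len(out) == 18
        np.testing.assert_allclose(
            out["p_sidak"], np.clip(1 - (1 - out["p_raw"]) ** 18, 0, 1), atol=1e-12
        )

    def test_detects_injected_group_difference(self):
        rng = np.random.default_rng(10)
        rows = [
            {"group": g, "age": a, "fold": (3.0 if g == "FS" else 0.0) + rng.normal(0, 0.3)}
            for g in ("intact", "control", "FS")
            for a in ("P14", "P21")
            for _ in range(6)
        ]
        out = pairwise_contrasts(pd.DataFrame(rows))
        fs = out[out["contrast"].str.startswith("FS vs intact") | out["contrast"].str.contains("FS")]
        assert (fs[fs["contrast"].str.contains(r"FS", regex=True)]["p_sidak"] < 0.05).any()


class TestAssumptionChecks:
    def test_normal_cell_passes_shapiro(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"group": "intact", "age": "P14", "fold": rng.normal(size=50)}
        )
        rep = assumption_checks(df)
        assert rep.shapiro.iloc[0]["p"] > 0.01

    def test_equal_variance_cells_pass_levene(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "group": ["intact"] * 30 + ["FS"] * 30,
                "age": "P14",
                "fold": np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)]),
            }
        )
        rep = assumption_checks(df)
        assert rep.levene_p > 0.01

    def test_tiny_cell_not_evaluated(self):
        df = pd.DataFrame({"group": ["intact"] * 2, "age": "P14", "fold": [1.0, 2.0]})
        rep = assumption_checks(df)
        assert rep.shapiro.iloc[0]["status"] == "not evaluated"
        assert rep.levene_stat is None


class TestAnalyzeTarget:
    def test_end_to_end_on_known_effects(self):
        from refstab import cq_data, simulate

        params = simulate.developmental_scenario(n_per_cell=10, seed=3)
        meas, ann, truth = simulate.simulate_cq(params)
        values = cq_data.collapse_replicates(meas).complete_cases()
        res = expression.analyze_target(
            values, ann, target="S100b", refs=["Ppia", "Rpl13a"]
        )
        assert res.calibrator_group == "intact" and res.calibrator_age == "P14"
        assert (res.fold_table["fold"] > 0).all()
        # injected P21-onset doubling should surface as a significant age effect
        anova = res.anova.set_index("effect")
        assert anova.at["age", "p"] < 0.01
        assert res.scale == "log2"
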