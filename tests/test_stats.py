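"""Inferential toolkit: Welch t, mixed ANOVA + GG epsilon, contrasts, OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sagame.stats import (gg_epsilon, linear_contrast, mixed_anova, nested_f,
                          ols_regression, pearson_r, welch_t)


def test_welch_identical_samples():
    r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t == 0.0
    assert r.p == pytest.approx(1.0)
    assert r.cohen_d == 0.0


def test_welch_hand_computed_example():
    # means 2 and 4; variances 1 and 4; se^2 = 1/3 + 4/3
    r = welch_t([1, 2, 3], [2, 4, 6])
    assert r.t == pytest.approx(-2 / np.sqrt(5 / 3), abs=1e-9)
    df = (5 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2)
    assert r.df == pytest.approx(df, abs=1e-9)  # ~2.94
    # cross-check p against scipy's Welch test
    t_sp, p_sp = sps.ttest_ind([1, 2, 3], [2, 4, 6], equal_var=False)
    assert r.t == pytest.approx(t_sp) and r.p == pytest.approx(p_sp)


def test_welch_df_collapses_to_pooled_for_equal_var_equal_n():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 30)
    b = a + 0.5  # identical variance by construction
    r = welch_t(a, b)
    assert r.df == pytest.approx(58, abs=1e-9)


def test_welch_antisymmetry_and_cohen_d_variants():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 20), rng.normal(0.8, 2, 25)
    r1, r2 = welch_t(a, b), welch_t(b, a)
    assert r1.t == pytest.approx(-r2.t)
    assert r1.p == pytest.approx(r2.p)
    d_unpooled = welch_t(a, b, pooled_d=False).cohen_d
    assert d_unpooled != r1.cohen_d
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


# ------------------------------------------------------------ mixed ANOVA

def random_mixed_frame(rng, n1=12, n2=9, k=3, group_shift=0.5, phase_slope=0.3):
    rows = []
    for i in range(n1 + n2):
        g = "a" if i < n1 else "b"
        subj_eff = rng.normal(0, 1)
        for ph in range(k):
            y = (subj_eff + (group_shift if g == "b" else 0)
                 + phase_slope * ph + rng.normal(0, 0.8))
            rows.append({"participant_id": f"s{i}", "group": g,
                         "phase": f"p{ph}", "value": y})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(42)
    for rep in range(5):
        df = random_mixed_frame(rng)
        mine = mixed_anova(df, dv="value", within="phase",
                           subject="participant_id", between="group")
        ref = pg.mixed_anova(data=df, dv="value", within="phase",
                             subject="participant_id", between="group",
                             correction=True).set_index("Source")
        assert mine.effects["group"].F == pytest.approx(ref.loc["group", "F"])
        assert mine.effects["phase"].F == pytest.approx(ref.loc["phase", "F"])
        assert mine.effects["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"])
        for eff, src in (("group", "group"), ("phase", "phase"),
                         ("interaction", "Interaction")):
            assert mine.effects[eff].p == pytest.approx(ref.loc[src, "p_unc"])
            assert mine.effects[eff].partial_eta_sq == pytest.approx(
                ref.loc[src, "np2"])


def test_gg_epsilon_matches_pingouin_convention():
    import pingouin as pg

    rng = np.random.default_rng(3)
    wide = rng.normal(size=(25, 3)) @ np.array([[1, 0.3, 0.1],
                                                [0, 1, 0.4], [0, 0, 1.5]])
    eps_ref = float(pg.epsilon(pd.DataFrame(wide), correction="gg"))
    assert gg_epsilon(wide) == pytest.approx(eps_ref, abs=1e-10)


def test_constant_phase_means_give_zero_phase_f():
    rows = []
    for i in range(8):
        base = float(i)
        for ph in range(3):
            rows.append({"participant_id": f"s{i}", "group": "a" if i < 4 else "b",
                         "phase": f"p{ph}", "value": base})
    res = mixed_anova(pd.DataFrame(rows))
    assert res.effects["phase"].F == pytest.approx(0.0, abs=1e-20)


def test_epsilon_bounds_for_three_levels():
    rng = np.random.default_rng(7)
    for _ in range(30):
        wide = rng.normal(size=(10, 3)) * rng.uniform(0.2, 3, size=3)
        eps = gg_epsilon(wide)
        assert 0.5 - 1e-12 <= eps <= 1.0 + 1e-12
    assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0


def test_epsilon_near_one_under_sphericity():
    # compound-symmetric data satisfy sphericity; epsilon estimates near 1
    rng = np.random.default_rng(11)
    eps = []
    for _ in range(100):
        subj = rng.normal(0, 1, (40, 1))
        wide = subj + rng.normal(0, 1, (40, 3))
        eps.append(gg_epsilon(wide))
    assert 0.9 <= np.mean(eps) <= 1.0


def test_missing_cells_rejected():
    df = random_mixed_frame(np.random.default_rng(0))
    with pytest.raises(ValueError, match="missing"):
        mixed_anova(df.iloc[:-1])


def test_anova_dfs_and_gg_correction_factor():
    df = random_mixed_frame(np.random.default_rng(5))
    res = mixed_anova(df)
    ph = res.effects["phase"]
    assert (ph.df1, ph.df2) == (2.0, 38.0)
    assert ph.df1_gg == pytest.approx(res.gg_epsilon * 2)
    assert ph.df2_gg == pytest.approx(res.gg_epsilon * 38)
    assert 0 <= ph.partial_eta_sq <= 1


# ------------------------------------------------------------- contrasts

def test_contrast_flat_profile_gives_zero():
    res = linear_contrast(np.full((6, 3), 2.5))
    assert res.mean_L == 0.0
    assert res.t == 0.0
    assert res.degenerate


def test_contrast_noise_free_slope_flagged_degenerate():
    res = linear_contrast(np.tile([0.0, 1.0, 2.0], (5, 1)))
    assert res.mean_L == pytest.approx(2.0)
    assert res.degenerate


def test_contrast_recovers_linear_trend():
    rng = np.random.default_rng(2)
    delta = 0.4
    means = []
    for _ in range(200):
        Y = rng.normal(0, 1, (20, 3)) + np.arange(3) * delta
        means.append(linear_contrast(Y).mean_L)
    assert np.mean(means) == pytest.approx(2 * delta, abs=0.05)


# ------------------------------------------------------------ regression

def test_exact_linear_fit():
    x = np.arange(10, dtype=float)
    y = 2.0 + 3.0 * x
    r = ols_regression(y, x[:, None], names=["x"])
    assert r.r_sq == pytest.approx(1.0)
    assert r.adj_r_sq == pytest.approx(1.0)
    assert r.coef[1] == pytest.approx(3.0)


def test_single_predictor_matches_normal_equations():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 40)
    y = 1.5 + 0.7 * x + rng.normal(0, 0.5, 40)
    r = ols_regression(y, x[:, None])
    beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    alpha = y.mean() - beta * x.mean()
    assert r.coef[1] == pytest.approx(beta, abs=1e-10)
    assert r.coef[0] == pytest.approx(alpha, abs=1e-10)
    # residual orthogonality
    resid = y - (r.coef[0] + r.coef[1] * x)
    assert abs(resid @ x) < 1e-8


def test_null_adj_r_sq_centers_on_zero():
    rng = np.random.default_rng(6)
    vals = []
    for _ in range(100):
        y = rng.normal(0, 1, 1000)
        x = rng.normal(0, 1, (1000, 1))
        vals.append(ols_regression(y, x).adj_r_sq)
    assert abs(np.mean(vals)) < 0.02


def test_rank_deficiency_rejected():
    x = np.ones((10, 1))  # collinear with the intercept
    with pytest.raises(ValueError, match="rank"):
        ols_regression(np.arange(10, dtype=float), x)


def test_nested_f_hand_computation():
    rng = np.random.default_rng(8)
    x1 = rng.normal(0, 1, 30)
    x2 = rng.normal(0, 1, 30)
    y = 0.5 * x1 + 0.8 * x2 + rng.normal(0, 1, 30)
    reduced = ols_regression(y, x1[:, None], names=["x1"])
    full = ols_regression(y, np.column_stack([x1, x2]), names=["x1", "x2"])
    cmp = nested_f(reduced, full)
    F = ((full.r_sq - reduced.r_sq) / 1) / ((1 - full.r_sq) / (30 - 2 - 1))
    assert cmp.F == pytest.approx(F, abs=1e-12)
    assert cmp.df1 == 1 and cmp.df2 == 27
    assert cmp.delta_r_sq == pytest.approx(full.r_sq - reduced.r_sq)
    # identical models
    same = nested_f(full, full)
    assert same.F == pytest.approx(0.0) and same.delta_r_sq == pytest.approx(0.0)
    with pytest.raises(ValueError, match="nested"):
        nested_f(full, reduced)


def test_pearson_r_basics():
    x = np.arange(10, dtype=float)
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_r(x, np.zeros(10))
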