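"""Repeated-measures ANOVA, Tukey-adjusted contrasts and paired t-tests,
cross-checked against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eightart.stats import paired_t, posthoc_tukey, rm_anova_2x2

CELLS = [("MI", "success"), ("MI", "error"), ("IS", "success"), ("IS", "error")]


def long_table(Y):
    rows = []
    for i, row in enumerate(np.asarray(Y, float)):
        for (cond, acc), v in zip(CELLS, row):
            rows.append(dict(participant=i, condition=cond, accuracy=acc, value=v))
    return pd.DataFrame(rows)


def oracle_ss(Y):
    """Brute-force sums-of-squares decomposition of the 2×2 within design."""
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    a = np.array([0, 1, 0, 1])
    b = np.array([0, 0, 1, 1])
    grand = Y.mean()
    out = {}
    for name, lev in (("accuracy", a), ("condition", b)):
        m = np.array([Y[:, lev == k].mean() for k in (0, 1)])
        ss_eff = 2 * n * ((m - grand) ** 2).sum()
        ss_err = 0.0
        for i in range(n):
            for k in (0, 1):
                cell = Y[i, lev == k].mean()
                ss_err += 2 * (cell - m[k] - Y[i].mean() + grand) ** 2
        out[name] = (ss_eff, ss_err)
    mab = np.array([[Y[:, (a == x) & (b == y)].mean() for y in (0, 1)] for x in (0, 1)])
    ma = np.array([Y[:, a == x].mean() for x in (0, 1)])
    mb = np.array([Y[:, b == y].mean() for y in (0, 1)])
    ss_ab = n * ((mab - ma[:, None] - mb[None, :] + grand) ** 2).sum()
    ss_err = 0.0
    for i in range(n):
        for j in range(4):
            x, y = a[j], b[j]
            mia = Y[i, a == x].mean()
            mib = Y[i, b == y].mean()
            r = Y[i, j] - mab[x, y] - mia - mib + ma[x] + mb[y] + Y[i].mean() - grand
            ss_err += r * r
    out["interaction"] = (ss_ab, ss_err)
    return out


def f_from_ss(ss_eff, ss_err, n):
    return (ss_eff / 1.0) / (ss_err / (n - 1)) if ss_err > 0 else np.inf


def test_identical_cells_give_zero_f():
    res = rm_anova_2x2(long_table(np.full((6, 4), 5.0)))
    for eff in res.effects.values():
        assert eff.F == 0.0


def test_anova_matches_oracle_on_random_data(rng):
    for _ in range(20):
        n = rng.integers(4, 9)
        Y = rng.normal(0, 1, (n, 4)) + rng.normal(0, 1, (n, 1))
        res = rm_anova_2x2(long_table(Y))
        orc = oracle_ss(Y)
        for name, (ss_eff, ss_err) in orc.items():
            e = res.effects[name]
            assert e.F == pytest.approx(f_from_ss(ss_eff, ss_err, n), rel=1e-10)
            assert e.partial_eta_sq == pytest.approx(
                ss_eff / (ss_eff + ss_err), rel=1e-10
            )


def test_anova_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM

    Y = rng.normal(0, 1, (8, 4)) + rng.normal(0, 2, (8, 1))
    table = long_table(Y)
    res = rm_anova_2x2(table)
    sm = AnovaRM(table, "value", "participant",
                 within=["condition", "accuracy"]).fit().anova_table
    assert res.effects["condition"].F == pytest.approx(
        sm.loc["condition", "F Value"], rel=1e-8
    )
    assert res.effects["accuracy"].F == pytest.approx(
        sm.loc["accuracy", "F Value"], rel=1e-8
    )
    assert res.effects["interaction"].F == pytest.approx(
        sm.loc["condition:accuracy", "F Value"], rel=1e-8
    )


def test_anova_matches_pingouin(rng):
    import pingouin as pg

    Y = rng.normal(0, 1, (10, 4))
    table = long_table(Y)
    res = rm_anova_2x2(table)
    aov = pg.rm_anova(
        data=table, dv="value", within=["condition", "accuracy"],
        subject="participant", detailed=True,
    )
    f = dict(zip(aov["Source"], aov["F"]))
    assert res.effects["condition"].F == pytest.approx(f["condition"], rel=1e-6)
    assert res.effects["accuracy"].F == pytest.approx(f["accuracy"], rel=1e-6)
    assert res.effects["interaction"].F == pytest.approx(
        f["condition * accuracy"], rel=1e-6
    )


def test_f_equals_squared_paired_t(rng):
    """In the 2×2 within design each effect's F is the squared paired t of
    the corresponding difference scores."""
    Y = rng.normal(0, 1, (12, 4))
    res = rm_anova_2x2(long_table(Y))
    d_acc = (Y[:, 1] + Y[:, 3]) / 2 - (Y[:, 0] + Y[:, 2]) / 2
    d_cond = (Y[:, 2] + Y[:, 3]) / 2 - (Y[:, 0] + Y[:, 1]) / 2
    d_int = (Y[:, 1] - Y[:, 0]) - (Y[:, 3] - Y[:, 2])
    for name, d in (("accuracy", d_acc), ("condition", d_cond), ("interaction", d_int)):
        t = paired_t(d).t
        assert res.effects[name].F == pytest.approx(t**2, rel=1e-9)


def test_incomplete_participants_dropped(rng):
    Y = rng.normal(0, 1, (6, 4))
    table = long_table(Y)
    table = table[~((table.participant == 5) & (table.accuracy == "error")
                    & (table.condition == "IS"))]
    with pytest.warns(UserWarning, match="incomplete"):
        res = rm_anova_2x2(table)
    assert res.n_complete == 5 and res.dropped == [5]


def test_too_few_cases_raise():
    with pytest.raises(ValueError):
        rm_anova_2x2(long_table(np.zeros((2, 4))))


class TestTukey:
    def test_identical_cells_p_near_one(self, rng):
        noise = rng.normal(0, 1e-6, (8, 4))
        contrasts = posthoc_tukey(long_table(noise + 5.0))
        # all cells share the same mean: no contrast is significant
        assert all(c.p > 0.5 for c in contrasts)

    def test_adjusted_p_at_least_paired_p(self, rng):
        Y = rng.normal(0, 1, (10, 4)) + [0.0, 0.5, 0.1, 0.3]
        contrasts = posthoc_tukey(long_table(Y))
        for c in contrasts:
            i = CELLS.index(c.cell_a)
            j = CELLS.index(c.cell_b)
            p_t = paired_t(Y[:, i], Y[:, j]).p
            assert c.p >= p_t - 1e-12

    def test_planted_deviant_cell(self, rng):
        Y = rng.normal(0, 0.3, (15, 4))
        Y[:, 1] += 3.0  # one deviant cell
        contrasts = posthoc_tukey(long_table(Y))
        for c in contrasts:
            involves = CELLS[1] in (c.cell_a, c.cell_b)
            assert (c.p < 0.05) == involves


class TestPairedT:
    def test_equal_samples(self):
        with pytest.warns(UserWarning):
            c = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t == 0.0 and c.p == 1.0

    def test_hand_arithmetic(self):
        c = paired_t([1.0, 2.0, 3.0])
        assert c.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-12)
        assert c.cohen_d == pytest.approx(2.0)

    def test_one_sided_direction(self):
        d = [1.0, 1.5, 2.0, 0.5]
        assert paired_t(d, sided="one", direction="greater").p < 0.05
        assert paired_t(d, sided="one", direction="less").p > 0.95

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            c = paired_t([2.0, 2.0, 2.0])
        assert c.p == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(4, 10),
    scale=st.floats(0.1, 10.0),
)
def test_anova_oracle_property(seed, n, scale):
    rng = np.random.default_rng(seed)
    Y = rng.normal(0, scale, (n, 4)) + rng.normal(0, scale, (n, 1))
    res = rm_anova_2x2(long_table(Y))
    for name, (ss_eff, ss_err) in oracle_ss(Y).items():
        assert res.effects[name].F == pytest.approx(
            f_from_ss(ss_eff, ss_err, n), rel=1e-9, abs=1e-12
        )
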