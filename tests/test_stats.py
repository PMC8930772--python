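"""Blocked ANOVA and Holm-Sidak comparisons against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from dropseg.quant import FieldSummary
from dropseg.stats import (
    build_experiment_table,
    holm_sidak,
    linked_anova,
    report,
    significance_stars,
)


def _table(values: np.ndarray, strains=None) -> pd.DataFrame:
    s, b = values.shape
    strains = strains or [f"s{i}" for i in range(s)]
    rows = [
        {"strain": strains[i], "experiment_id": j + 1, "value": values[i, j]}
        for i in range(s)
        for j in range(b)
    ]
    return pd.DataFrame(rows)


def _fs(strain, exp, field, mean_ld, pct=0.0):
    return FieldSummary(strain, exp, field, 10, mean_ld, pct, None)


def test_experiment_table_means_and_shape():
    fields = [
        _fs("a", 1, 1, 2.0), _fs("a", 1, 2, 3.0), _fs("a", 1, 3, 4.0),
        _fs("a", 2, 1, 5.0),
        _fs("b", 1, 1, 1.0), _fs("b", 2, 1, 2.0),
    ]
    table = build_experiment_table(fields, "mean_ld_per_cell")
    assert len(table) == 4
    a1 = table.query("strain == 'a' and experiment_id == 1")["value"].iloc[0]
    assert a1 == pytest.approx(3.0)
    a2 = table.query("strain == 'a' and experiment_id == 2")["value"].iloc[0]
    assert a2 == pytest.approx(5.0)


def test_experiment_table_incomplete_design_raises():
    fields = [_fs("a", 1, 1, 2.0), _fs("a", 2, 1, 3.0), _fs("b", 1, 1, 1.0)]
    with pytest.raises(ValueError, match="missing"):
        build_experiment_table(fields, "mean_ld_per_cell")


def test_anova_no_strain_effect_gives_zero_F():
    values = np.array([[1.0, 5.0, 3.0], [1.0, 5.0, 3.0]])  # block means only
    res = linked_anova(_table(values))
    assert res.ss_strain == pytest.approx(0.0, abs=1e-12)
    assert res.F == pytest.approx(0.0, abs=1e-12)


def test_anova_matches_definitional_bruteforce(rng):
    """SS terms and F match explicit definitional sums on random tables."""
    for _ in range(5):
        y = rng.normal(size=(3, 4))
        res = linked_anova(_table(y))
        grand = y.mean()
        ss_strain = sum(4 * (y[i].mean() - grand) ** 2 for i in range(3))
        ss_block = sum(3 * (y[:, j].mean() - grand) ** 2 for j in range(4))
        ss_total = ((y - grand) ** 2).sum()
        ss_res = ss_total - ss_strain - ss_block
        assert res.ss_strain == pytest.approx(ss_strain, rel=1e-10)
        assert res.ss_block == pytest.approx(ss_block, rel=1e-10)
        assert res.ss_residual == pytest.approx(ss_res, rel=1e-10)
        assert res.F == pytest.approx((ss_strain / 2) / (ss_res / 6), rel=1e-10)
        assert res.df_strain == 2 and res.df_block == 3 and res.df_residual == 6


def test_anova_matches_statsmodels(rng):
    """Cross-check against an independent two-way additive OLS ANOVA."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = rng.normal(size=(4, 3))
    table = _table(y)
    fit = ols("value ~ C(strain) + C(experiment_id)", data=table).fit()
    sm_table = sm.stats.anova_lm(fit, typ=2)
    res = linked_anova(table)
    assert res.ss_strain == pytest.approx(sm_table.loc["C(strain)", "sum_sq"], rel=1e-8)
    assert res.ss_residual == pytest.approx(sm_table.loc["Residual", "sum_sq"], rel=1e-8)
    assert res.F == pytest.approx(sm_table.loc["C(strain)", "F"], rel=1e-8)
    assert res.p_value == pytest.approx(sm_table.loc["C(strain)", "PR(>F)"], rel=1e-8)


def test_anova_block_shift_invariance(rng):
    y = rng.normal(size=(3, 4))
    base = linked_anova(_table(y))
    shifted = y.copy()
    shifted[:, 2] += 7.5  # constant added to one block
    res = linked_anova(_table(shifted))
    assert res.F == pytest.approx(base.F, rel=1e-8)
    assert res.ss_strain == pytest.approx(base.ss_strain, rel=1e-8)
    assert res.ss_block != pytest.approx(base.ss_block, rel=1e-3)


def test_anova_rejects_degenerate_designs(rng):
    with pytest.raises(ValueError):
        linked_anova(_table(rng.normal(size=(1, 4))))
    with pytest.raises(ValueError):
        linked_anova(_table(rng.normal(size=(3, 1))))


def test_holm_sidak_closed_form_adjustments(rng):
    y = rng.normal(size=(3, 4))
    table = _table(y, strains=["a", "b", "c"])
    anova = linked_anova(table)
    res = holm_sidak([("a", "b"), ("a", "c")], table, anova)
    # independently recompute: t on pooled MS_res, Sidak step-down
    from scipy import stats as sps

    se = np.sqrt(2 * anova.ms_residual / 4)
    praw = {}
    for pair in [("a", "b"), ("a", "c")]:
        d = anova.strain_means[pair[0]] - anova.strain_means[pair[1]]
        praw[pair] = 2 * sps.t.sf(abs(d / se), 6)
    order = sorted(praw, key=praw.get)
    adj0 = 1 - (1 - praw[order[0]]) ** 2
    adj1 = max(adj0, praw[order[1]])
    expected = {order[0]: adj0, order[1]: adj1}
    for r in res:
        assert r.p_raw == pytest.approx(praw[r.pair], rel=1e-10)
        assert r.p_adjusted == pytest.approx(expected[r.pair], rel=1e-10)
        assert r.p_adjusted >= r.p_raw


def test_holm_sidak_worked_example():
    """m=2 with raw p (0.01, 0.04): adjusted (1-0.99^2, 0.04)."""
    from dropseg.stats import _step_down_adjust

    adj = _step_down_adjust(np.array([0.01, 0.04]), "sidak")
    assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
    assert adj[1] == pytest.approx(0.04)
    assert _step_down_adjust(np.array([0.05]), "sidak")[0] == pytest.approx(0.05)
    assert _step_down_adjust(np.array([1.0, 0.2]), "sidak")[0] == pytest.approx(1.0)
    holm = _step_down_adjust(np.array([0.01, 0.04]), "holm")
    assert holm[0] == pytest.approx(0.02) and holm[1] == pytest.approx(0.04)


def test_holm_sidak_monotone_and_dominating(rng):
    from dropseg.stats import _step_down_adjust

    for _ in range(20):
        p = rng.uniform(0, 1, size=rng.integers(1, 8))
        adj = _step_down_adjust(p, "sidak")
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1.0).all()


def test_holm_sidak_unknown_strain_raises(rng):
    table = _table(rng.normal(size=(2, 3)), strains=["a", "b"])
    anova = linked_anova(table)
    with pytest.raises(ValueError, match="unknown strain"):
        holm_sidak([("a", "zz")], table, anova)


def test_stars_convention():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == "NS"


def test_report_roundtrip_and_empty(tmp_path, rng):
    table = _table(rng.normal(size=(2, 3)), strains=["wt", "mut"])
    anova = linked_anova(table)
    res = holm_sidak([("wt", "mut")], table, anova)
    frame = report(res, tmp_path / "pairwise.csv", anova)
    back = pd.read_csv(tmp_path / "pairwise.csv")
    pd.testing.assert_frame_equal(frame, back)
    empty = report([], tmp_path / "empty.csv")
    assert list(pd.read_csv(tmp_path / "empty.csv").columns) == list(empty.columns)
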