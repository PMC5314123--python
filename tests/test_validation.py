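"""qPCR quantification, t-tests, two-way ANOVA and Fisher's LSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import crossmeth as cm


def _ct_table(rows, cols=("sample_id", "group", "ct_target", "ct_reference")):
    return pd.DataFrame(rows, columns=list(cols))


# ------------------------------------------------------------------ ddCt ----

def test_calibrator_mean_fold_is_one():
    table = _ct_table([("a", "control", 24.0, 20.0), ("b", "control", 26.0, 22.0),
                       ("c", "stress", 25.0, 20.0)])
    out = cm.delta_delta_ct(table)
    cal = out[out.group == "control"]
    assert cal.delta_delta_ct.mean() == pytest.approx(0.0)
    assert np.exp2(-cal.delta_delta_ct.mean()) == pytest.approx(1.0)


def test_one_cycle_more_halves_the_fold():
    """treated dCt 5 vs calibrator mean dCt 4 -> ddCt 1 -> fold 0.5."""
    table = _ct_table([("a", "control", 24.0, 20.0), ("b", "stress", 25.0, 20.0)])
    out = cm.delta_delta_ct(table)
    assert out.loc[out.group == "stress", "fold_change"].iloc[0] == pytest.approx(0.5)
    assert out.loc[out.group == "stress",
                   "percent_of_calibrator"].iloc[0] == pytest.approx(50.0)


def test_sample_at_calibrator_mean_has_fold_one():
    table = _ct_table([("a", "control", 24.0, 20.0), ("b", "stress", 24.0, 20.0)])
    out = cm.delta_delta_ct(table)
    assert out.fold_change.iloc[1] == pytest.approx(1.0)


@given(st.integers(0, 2**31 - 1))
def test_ddct_matches_independent_formula(seed):
    rng = np.random.default_rng(seed)
    n = 8
    table = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["control"] * 4 + ["stress"] * 4,
        "ct_target": rng.uniform(18, 32, n),
        "ct_reference": rng.uniform(14, 22, n),
    })
    out = cm.delta_delta_ct(table)
    dct = table.ct_target.to_numpy() - table.ct_reference.to_numpy()
    ddct = dct - dct[:4].mean()
    assert np.allclose(out.fold_change, 2.0 ** (-ddct))
    assert (out.fold_change > 0).all()


def test_age_stratified_calibration():
    rows = [("a", "control", "PND7", 25.0, 20.0),
            ("b", "stress", "PND7", 26.0, 20.0),
            ("c", "control", "PND62", 22.0, 20.0),
            ("d", "stress", "PND62", 23.0, 20.0)]
    table = pd.DataFrame(rows, columns=["sample_id", "group", "age",
                                        "ct_target", "ct_reference"])
    out = cm.delta_delta_ct(table, by=["age"])
    assert np.allclose(out[out.group == "stress"].fold_change, 0.5)


def test_missing_reference_ct_rejected():
    table = _ct_table([("a", "control", 24.0, np.nan)])
    with pytest.raises(cm.InputError, match="ct_reference"):
        cm.delta_delta_ct(table)


# ------------------------------------------------------- MeDIP enrichment ----

def test_equal_channels_give_unit_enrichment():
    rows = [("a", "control", 25.0, 25.0), ("b", "stress", 27.0, 27.0)]
    table = pd.DataFrame(rows, columns=["sample_id", "group", "ct_bound",
                                        "ct_input"])
    per_sample, summary = cm.medip_enrichment(table)
    assert np.allclose(per_sample.enrichment, 1.0)


def test_one_cycle_lower_bound_doubles_enrichment():
    rows = [("a", "control", 25.0, 20.0), ("b", "control", 25.0, 20.0),
            ("c", "stress", 24.0, 20.0), ("d", "stress", 24.0, 20.0)]
    table = pd.DataFrame(rows, columns=["sample_id", "group", "ct_bound",
                                        "ct_input"])
    _, summary = cm.medip_enrichment(table)
    means = summary.set_index("group")["mean"]
    assert means["stress"] / means["control"] == pytest.approx(2.0)


def test_planted_hypermethylation_detected_by_t_test():
    """+1 log2 planted in the bound channel -> significant enrichment at 4v4."""
    rng = np.random.default_rng(12)
    rows = []
    for i in range(4):
        rows.append((f"c{i}", "control", 25.0 + rng.normal(0, 0.2), 20.0))
        rows.append((f"s{i}", "stress", 24.0 + rng.normal(0, 0.2), 20.0))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "ct_bound",
                                        "ct_input"])
    per_sample, _ = cm.medip_enrichment(table)
    res = cm.welch_t_two_tailed(
        per_sample[per_sample.group == "stress"].enrichment,
        per_sample[per_sample.group == "control"].enrichment)
    assert res.p_value < 0.05 and res.significant


# ---------------------------------------------------------------- t-test ----

def test_identical_groups_not_significant():
    res = cm.welch_t_two_tailed([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0) and not res.significant


def test_welch_hand_example():
    res = cm.welch_t_two_tailed([2, 4, 6, 8], [1, 2, 3, 4])
    assert abs(res.statistic) == pytest.approx(1.7321, abs=1e-4)
    assert res.df == pytest.approx(4.412, abs=1e-3)


def test_null_rejection_rate_close_to_alpha():
    rng = np.random.default_rng(4)
    hits = sum(
        cm.welch_t_two_tailed(rng.normal(0, 1, 5), rng.normal(0, 1, 5)).significant
        for _ in range(1000))
    # binomial 99% CI around 0.05 at 1000 reps
    assert abs(hits / 1000 - 0.05) < 2.5758 * np.sqrt(0.05 * 0.95 / 1000)


# ----------------------------------------------------------------- ANOVA ----

def balanced_2x2():
    rows = []
    cells = {("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
             ("a2", "b1"): [5, 6], ("a2", "b2"): [7, 8]}
    for (a, b), values in cells.items():
        rows += [(a, b, v) for v in values]
    return pd.DataFrame(rows, columns=["group", "age", "value"])


def test_balanced_2x2_closed_form():
    res = cm.two_way_anova(balanced_2x2())
    assert res.terms["group"].ss == pytest.approx(32.0, rel=1e-9)
    assert res.terms["age"].ss == pytest.approx(8.0, rel=1e-9)
    assert res.terms["interaction"].ss == pytest.approx(0.0, abs=1e-9)
    assert res.residual_ss == pytest.approx(2.0, rel=1e-9)
    assert res.terms["group"].f == pytest.approx(64.0, rel=1e-9)
    assert res.terms["age"].f == pytest.approx(16.0, rel=1e-9)


def test_df_accounting_and_ss_conservation_balanced():
    res = cm.two_way_anova(balanced_2x2())
    dfs = sum(t.df for t in res.terms.values()) + res.residual_df
    assert dfs == res.nobs - 1
    total = sum(t.ss for t in res.terms.values()) + res.residual_ss
    y = balanced_2x2().value
    assert total == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-9)


def test_all_equal_values_convention():
    df = balanced_2x2().assign(value=3.0)
    res = cm.two_way_anova(df)
    for term in res.terms.values():
        assert term.ss == 0.0 and term.p_value == 1.0


def test_empty_cell_names_the_cell():
    df = balanced_2x2()
    df = df[~((df.group == "a2") & (df.age == "b1"))]
    with pytest.raises(cm.InputError, match="a2.*b1"):
        cm.two_way_anova(df)


def _ss_by_model_comparison(df, term):
    """Type-II SS via residual-sum-of-squares differences of nested OLS fits."""
    def rss(formula_terms):
        X = [np.ones(len(df))]
        for t in formula_terms:
            if t == "A":
                X.append((df.group == "a2").to_numpy(float))
            elif t == "B":
                X.append((df.age == "b2").to_numpy(float))
            elif t == "AB":
                X.append(((df.group == "a2") & (df.age == "b2")).to_numpy(float))
        X = np.column_stack(X)
        y = df.value.to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return ((y - X @ beta) ** 2).sum()

    if term == "A":
        return rss(["B"]) - rss(["A", "B"])
    if term == "B":
        return rss(["A"]) - rss(["A", "B"])
    return rss(["A", "B"]) - rss(["A", "B", "AB"])


@given(st.integers(0, 2**31 - 1))
def test_type2_ss_matches_model_comparison_oracle_unbalanced(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            for _ in range(int(rng.integers(2, 6))):
                rows.append((a, b, rng.normal(0, 1)))
    df = pd.DataFrame(rows, columns=["group", "age", "value"])
    res = cm.two_way_anova(df, ss_type=2)
    assert res.terms["group"].ss == pytest.approx(_ss_by_model_comparison(df, "A"),
                                                  abs=1e-8)
    assert res.terms["age"].ss == pytest.approx(_ss_by_model_comparison(df, "B"),
                                                abs=1e-8)
    assert res.terms["interaction"].ss == pytest.approx(
        _ss_by_model_comparison(df, "AB"), abs=1e-8)


def test_sequential_ss_available():
    res = cm.two_way_anova(balanced_2x2(), ss_type=1)
    assert res.terms["group"].ss == pytest.approx(32.0, rel=1e-9)


# ------------------------------------------------------------ Fisher LSD ----

def test_lsd_equal_means_p_one():
    df = balanced_2x2()
    # make group means equal within each age, keep residual variance
    df["value"] = [1, 2, 3, 4, 1, 2, 3, 4]
    res = cm.two_way_anova(df)
    lsd = cm.fisher_lsd(res)
    assert np.allclose(lsd.p_value, 1.0)


def test_lsd_hand_computed_example():
    """2x2 worked design: t = 4 / sqrt(0.5*(1/2+1/2)) = 5.657 on df 4."""
    res = cm.two_way_anova(balanced_2x2())
    lsd = cm.fisher_lsd(res)
    row = lsd[lsd.age == "b1"].iloc[0]
    assert abs(row.t) == pytest.approx(5.657, abs=1e-3)
    assert row.df == 4


def test_lsd_p_monotone_in_mean_difference():
    res = cm.two_way_anova(balanced_2x2())
    lsd = cm.fisher_lsd(res)
    ordered = lsd.reindex(lsd["diff"].abs().sort_values().index)
    assert (np.diff(ordered.p_value) <= 1e-12).all()


def test_interaction_rejection_rate_under_additive_truth():
    """No planted interaction: the interaction test rejects at ~alpha."""
    rng = np.random.default_rng(9)
    hits = 0
    reps = 500
    for _ in range(reps):
        rows = []
        for ai, a in enumerate(("a1", "a2")):
            for bi, b in enumerate(("b1", "b2", "b3")):
                mu = 0.5 * ai + 0.3 * bi  # purely additive truth
                rows += [(a, b, v) for v in rng.normal(mu, 1.0, 4)]
        df = pd.DataFrame(rows, columns=["group", "age", "value"])
        hits += cm.two_way_anova(df).terms["interaction"].p_value < 0.05
    assert abs(hits / reps - 0.05) < 2.5758 * np.sqrt(0.05 * 0.95 / reps)


def test_lsd_zero_mse_rejected():
    df = balanced_2x2()
    df["value"] = [1, 1, 3, 3, 5, 5, 7, 7]  # perfect cell fit
    res = cm.two_way_anova(df)
    with pytest.raises(cm.InputError, match="residual"):
        cm.fisher_lsd(res)
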