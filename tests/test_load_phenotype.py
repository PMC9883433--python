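"""Load grouping, rank tests, TMB, immune fractions and Cox survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal, mannwhitneyu

from rdvload.load_phenotype import (
    absolute_immune_fraction,
    assign_load_groups,
    compute_tmb,
    cox_survival,
    kruskal_wallis,
    load_dose_association,
    mann_whitney,
)


# --- load groups ----------------------------------------------------------

def test_load_groups_count_genes_not_variants():
    matrix = pd.DataFrame(
        {"G1": [2, 1, 0, 0], "G2": [0, 1, 0, 0], "G3": [0, 0, 3, 0]},
        index=list("abcd"),
    )
    lg = assign_load_groups(matrix, ["G1", "G2"], "set")
    assert lg.loc["a", "group"] == "one"     # 2 variants, 1 gene
    assert lg.loc["b", "group"] == "multi"   # 2 genes
    assert lg.loc["c", "group"] == "zero"    # RDV outside the set
    assert lg.loc["d", "group"] == "zero"
    # groups partition the cohort
    assert lg["group"].isin(["zero", "one", "multi"]).all()
    assert len(lg) == len(matrix)


def test_load_groups_empty_set_raises():
    with pytest.raises(ValueError):
        assign_load_groups(pd.DataFrame(index=["a"]), [], "empty")


def test_dose_association_skips_empty_multi_group():
    matrix = pd.DataFrame({"G1": [1, 0, 0, 0, 1, 0]}, index=list("abcdef"))
    lg = assign_load_groups(matrix, ["G1"], "s")
    y = pd.Series([1, 1, 1, 0, 0, 0], index=matrix.index)
    out = load_dose_association(lg, y)
    assert set(out) == {"one_vs_zero"}


def test_dose_association_monotone_in_expectation():
    rng = np.random.default_rng(21)
    n = 6000
    n_genes = (rng.random((n, 3)) < 0.06).astype(int)
    matrix = pd.DataFrame(n_genes, columns=["G1", "G2", "G3"],
                          index=[f"P{i}" for i in range(n)])
    total = n_genes.sum(axis=1)
    logit = -0.2 + np.log(1.6) * total  # additive per-gene log-odds
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
                  index=matrix.index)
    lg = assign_load_groups(matrix, ["G1", "G2", "G3"], "s")
    out = load_dose_association(lg, y)
    assert out["multi_vs_zero"].odds_ratio > out["one_vs_zero"].odds_ratio > 1.0


# --- Mann-Whitney ---------------------------------------------------------

def test_mann_whitney_enumeration_example():
    """x={1,2,3} vs y={4,5,6}: U=0, exact two-sided p = 2/20."""
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "exact"


def test_mann_whitney_identical_samples():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.statistic == 4.5  # n1 n2 / 2
    assert res.p_value == 1.0


def test_mann_whitney_all_tied_p_one():
    assert mann_whitney([5, 5], [5, 5, 5]).p_value == 1.0


def test_mann_whitney_matches_scipy_asymptotic():
    rng = np.random.default_rng(22)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.4, 1, 35)
    res = mann_whitney(x, y)
    u, p = mannwhitneyu(x, y, alternative="two-sided", use_continuity=False,
                        method="asymptotic")
    assert res.statistic == pytest.approx(u)
    assert res.p_value == pytest.approx(p, abs=1e-12)


def test_mann_whitney_exact_equals_brute_force_permutation():
    """Exact p equals exhaustive enumeration for every small instance tried,
    including ties."""
    from itertools import combinations

    from scipy.stats import rankdata

    rng = np.random.default_rng(23)
    for _ in range(10):
        n1, n2 = rng.integers(2, 6, 2)
        pooled = rng.integers(0, 5, n1 + n2).astype(float)  # heavy ties
        x, y = pooled[:n1], pooled[n1:]
        res = mann_whitney(x, y)
        ranks = rankdata(pooled)
        mu = n1 * n2 / 2
        obs = abs(res.statistic - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), int(n1)):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            total += 1
            hits += abs(u - mu) >= obs - 1e-9
        assert res.p_value == pytest.approx(hits / total)


def test_mann_whitney_normal_approx_close_to_exact_at_n8():
    rng = np.random.default_rng(24)
    devs = []
    for _ in range(20):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = mann_whitney(x, y).p_value
        approx = mann_whitney(x, y, exact_max=0).p_value
        devs.append(abs(exact - approx))
    assert max(devs) < 0.05


# --- Kruskal-Wallis -------------------------------------------------------

def test_kruskal_two_groups_equals_mann_whitney_normal():
    x = [1, 1, 2, 3, 3, 3, 4, 5, 9, 9]
    y = [2, 2, 3, 3, 4, 4, 5, 6, 7]
    kw = kruskal_wallis([x, y])
    mw = mann_whitney(x, y, exact_max=0)
    assert kw.p_value == pytest.approx(mw.p_value, abs=1e-10)


def test_kruskal_matches_scipy():
    rng = np.random.default_rng(25)
    groups = [rng.normal(m, 1, 20) for m in (0, 0.3, 0.6)]
    res = kruskal_wallis(groups)
    ref = kruskal(*groups)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_kruskal_constant_groups_h_zero():
    res = kruskal_wallis([[3, 3], [3, 3, 3]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_single_group_raises():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])


def test_kruskal_exact_equals_brute_force_enumeration():
    from itertools import combinations

    from scipy.stats import rankdata

    rng = np.random.default_rng(26)
    for _ in range(5):
        sizes = [int(s) for s in rng.integers(2, 4, 3)]
        pooled = rng.integers(0, 4, sum(sizes)).astype(float)
        groups = np.split(pooled, np.cumsum(sizes)[:-1])
        res = kruskal_wallis(list(groups), exact=True)
        # brute force using an independent H computation (scipy on permutations)
        ranks = rankdata(pooled)
        n = len(pooled)

        def h_of(parts):
            try:
                return kruskal(*parts).statistic
            except ValueError:
                return 0.0

        h_obs = h_of(list(groups))
        hits = total = 0
        for first in combinations(range(n), sizes[0]):
            rest1 = [i for i in range(n) if i not in set(first)]
            for second in combinations(rest1, sizes[1]):
                third = [i for i in rest1 if i not in set(second)]
                parts = [pooled[list(first)], pooled[list(second)], pooled[third]]
                total += 1
                hits += h_of(parts) >= h_obs - 1e-9
        assert res.statistic == pytest.approx(h_obs)
        assert res.p_value == pytest.approx(hits / total)


# --- TMB ------------------------------------------------------------------

def test_tmb_worked_example():
    counts = pd.DataFrame(
        {"missense": [50], "nonsense": [10], "frameshift": [10], "inframe": [6],
         "synonymous": [100]}
    )
    assert compute_tmb(counts).iloc[0] == 2.0  # 76 / 38


def test_tmb_zero_and_synonymous_excluded():
    counts = pd.DataFrame(
        {"missense": [0, 0], "nonsense": [0, 0], "frameshift": [0, 0],
         "inframe": [0, 0], "synonymous": [0, 500]}
    )
    assert (compute_tmb(counts) == 0.0).all()


def test_tmb_negative_count_raises():
    counts = pd.DataFrame({"missense": [-1], "nonsense": [0], "frameshift": [0],
                           "inframe": [0]})
    with pytest.raises(ValueError):
        compute_tmb(counts)


def test_tmb_linear_and_column_order_invariant():
    a = pd.DataFrame({"missense": [10], "nonsense": [2], "frameshift": [3],
                      "inframe": [4]})
    b = a[["inframe", "frameshift", "nonsense", "missense"]]
    assert compute_tmb(a).iloc[0] == compute_tmb(b).iloc[0]
    assert compute_tmb(3 * a).iloc[0] == 3 * compute_tmb(a).iloc[0]


# --- immune fractions -----------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 10.0), min_size=3, max_size=22),
    st.floats(0.0, 1.0),
)
def test_absolute_fractions_sum_to_leukocyte_fraction(raw, leuk):
    rel = np.array(raw) / np.sum(raw)
    df = pd.DataFrame([rel])
    out = absolute_immune_fraction(df, pd.Series([leuk]))
    assert out.sum(axis=1).iloc[0] == pytest.approx(leuk, abs=1e-9)


def test_absolute_fraction_examples_and_errors():
    rel = pd.DataFrame([[0.25, 0.75]], columns=["M1", "rest"])
    out = absolute_immune_fraction(rel, pd.Series([0.4]))
    assert out["M1"].iloc[0] == pytest.approx(0.10)
    assert (absolute_immune_fraction(rel, pd.Series([0.0])) == 0).all().all()
    with pytest.raises(ValueError):
        absolute_immune_fraction(rel, pd.Series([1.2]))
    with pytest.raises(ValueError):
        absolute_immune_fraction(pd.DataFrame([[0.2, 0.2]]), pd.Series([0.5]))


# --- Cox ------------------------------------------------------------------

def test_cox_constant_covariate_flagged():
    res = cox_survival(
        pd.Series([1.0, 2, 3, 4]), pd.Series([1, 1, 0, 1]), pd.Series([2.0] * 4)
    )
    assert not res.defined
    assert "variation" in res.note


def test_cox_recovers_planted_log_hazard():
    rng = np.random.default_rng(27)
    n = 2000
    x = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-0.5 * x))
    c = rng.uniform(0, 4, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    res = cox_survival(pd.Series(time + 1e-9), pd.Series(event), pd.Series(x))
    assert np.log(res.hazard_ratio) == pytest.approx(0.5, abs=0.1)
    assert res.p_value < 1e-6


def test_cox_drops_eventless_stratum():
    time = pd.Series([1.0, 2, 3, 4, 5, 6])
    event = pd.Series([1, 0, 1, 0, 0, 0])
    x = pd.Series([0.1, 0.9, 0.4, 0.2, 0.8, 0.3])
    strata = pd.Series(["a", "a", "a", "a", "b", "b"])
    res = cox_survival(time, event, x, strata)
    assert res.n == 4  # stratum b has no events
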