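from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from ctcpheno.simulate import simulate_composition_archetypes
from ctcpheno.stats import (
    benjamini_hochberg,
    clinical_associations,
    compare_subgroups,
    composition_matrix,
    mann_whitney_u,
    pca_composition,
)

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _enumeration_p(a, b):
    """Brute-force two-sided permutation p over all label assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(x, y):
        d = x[:, None] - y[None, :]
        return (d > 0).sum() + 0.5 * (d == 0).sum()

    u_obs = u_of(np.asarray(a, float), np.asarray(b, float))
    us = []
    for pick in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(pick)] = True
        us.append(u_of(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs + 1e-12).mean(), (us >= u_obs - 1e-12).mean()))


def test_u_fully_separated_samples():
    """a entirely below b: U = 0 and exact two-sided p = 2/20."""
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "exact"


def test_u_identical_multisets():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.u_statistic == pytest.approx(4.5)  # n^2 / 2
    assert res.p_value == 1.0


def test_exact_p_matches_scipy_exact():
    """Tie-free small samples: our enumeration equals scipy's exact method."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n1 = rng.integers(2, 5)
        n2 = rng.integers(2, 5)
        vals = rng.permutation(np.arange(20.0))[: n1 + n2]
        a, b = vals[:n1], vals[n1:]
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)


@settings(max_examples=40, deadline=None)
@given(
    a=st.lists(st.integers(0, 5), min_size=2, max_size=4),
    b=st.lists(st.integers(0, 5), min_size=2, max_size=4),
)
def test_exact_p_matches_enumeration_oracle_with_ties(a, b):
    """Permutation-oracle equivalence for all small samples, ties included."""
    ours = mann_whitney_u(a, b)
    assert ours.method == "exact"
    assert ours.p_value == pytest.approx(_enumeration_p(a, b), rel=1e-12)


def test_large_samples_use_normal_approx():
    rng = np.random.default_rng(1)
    res = mann_whitney_u(rng.normal(0, 1, 30), rng.normal(0.1, 1, 30))
    assert res.method == "normal_approx"
    ref = sps.mannwhitneyu(
        rng.normal(0, 1, 30), rng.normal(0, 1, 30), alternative="two-sided"
    )
    assert 0 < res.p_value <= 1


def test_normal_approx_close_to_scipy():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 20)
    ours = mann_whitney_u(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert ours.p_value == pytest.approx(ref.pvalue, rel=0.05)


def test_empty_sample_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney_u([], [1, 2])


def test_null_p_uniform_under_continuous_null():
    """U-test p under exchangeable continuous samples is uniform (KS)."""
    rng = np.random.default_rng(3)
    pvals = [
        mann_whitney_u(rng.normal(size=20), rng.normal(size=20)).p_value
        for _ in range(300)
    ]
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# subgroup comparisons
# ---------------------------------------------------------------------------


def test_compare_subgroups_requires_two_groups():
    vals = pd.DataFrame({"m": [1.0, 2.0]})
    with pytest.raises(ValueError, match=">= 2"):
        compare_subgroups(vals, ["g1", "g1"])


def test_compare_subgroups_detects_generator_direction():
    rng = np.random.default_rng(4)
    n = 120
    vals = pd.DataFrame(
        {
            "pCREB": np.concatenate(
                [rng.normal(1.5, 0.4, n), rng.normal(4.0, 0.4, n)]
            )
        }
    )
    labels = ["epithelial"] * n + ["early_EMT"] * n
    out = compare_subgroups(vals, labels)
    row = out.iloc[0]
    assert row["p"] < 0.05
    early_med = row["median1"] if row["group1"] == "early_EMT" else row["median2"]
    epi_med = row["median2"] if row["group1"] == "early_EMT" else row["median1"]
    assert early_med > epi_med


def test_compare_subgroups_null_marker_uniform_p():
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(200)[:200]:
        vals = pd.DataFrame({"m": rng.normal(size=60)})
        labels = ["a"] * 30 + ["b"] * 30
        pvals.append(compare_subgroups(vals, labels)["p"].iloc[0])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_compare_subgroups_bh_column_optional():
    rng = np.random.default_rng(6)
    vals = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
    labels = ["a"] * 20 + ["b"] * 20
    plain = compare_subgroups(vals, labels)
    assert "p_adj" not in plain.columns
    adj = compare_subgroups(vals, labels, adjust=True)
    assert (adj["p_adj"] >= adj["p"] - 1e-15).all()


# ---------------------------------------------------------------------------
# composition matrix and PCA
# ---------------------------------------------------------------------------


def test_composition_unit_vector_patient():
    comp = composition_matrix({"p1": np.array([2, 2, 2, 2])}, all_clusters=[1, 2, 3])
    assert comp.loc["p1"].tolist() == [0.0, 1.0, 0.0]


def test_composition_rows_sum_to_one():
    rng = np.random.default_rng(0)
    meta = {f"p{i}": rng.integers(1, 6, size=rng.integers(5, 40)) for i in range(8)}
    comp = composition_matrix(meta)
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)


def test_composition_zero_ctc_patient_rejected():
    with pytest.raises(ValueError, match="zero CTC"):
        composition_matrix({"p1": np.array([])})


def test_pca_reconstruction_and_variance_conservation():
    rng = np.random.default_rng(1)
    comp = pd.DataFrame(rng.dirichlet(np.ones(6), size=10))
    res = pca_composition(comp)
    # full-rank PCA reconstructs the centred matrix
    pca = PCA(n_components=res.scores.shape[1]).fit(comp.to_numpy())
    recon = pca.inverse_transform(pca.transform(comp.to_numpy()))
    np.testing.assert_allclose(recon, comp.to_numpy(), atol=1e-10)
    # score variance equals centred-input variance
    centred = comp.to_numpy() - comp.to_numpy().mean(axis=0)
    assert res.scores.to_numpy().var(axis=0).sum() == pytest.approx(
        centred.var(axis=0).sum(), rel=1e-10
    )
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_identical_patients_collapse():
    comp = pd.DataFrame([[0.5, 0.3, 0.2]] * 4, index=list("abcd"))
    res = pca_composition(comp, n_components=2)
    assert np.allclose(res.scores.to_numpy(), 0.0, atol=1e-12)


def test_pca_recovers_four_composition_archetypes():
    comp, truth = simulate_composition_archetypes(n_patients=24, n_clusters=8, seed=2)
    res = pca_composition(comp, seed=2)
    assert adjusted_rand_score(truth, res.patient_groups) >= 0.8


def test_pca_too_many_components_rejected():
    comp = pd.DataFrame(np.random.default_rng(0).dirichlet(np.ones(4), size=3))
    with pytest.raises(ValueError, match="components"):
        pca_composition(comp, n_components=10)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def _bh_bruteforce(p):
    """Step-up definition: adj_i = min over j>=rank(i) of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    sorted_p = p[order]
    adj_sorted = [
        min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
        for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_bh_matches_bruteforce_stepup():
    rng = np.random.default_rng(0)
    for n in (1, 2, 5, 11, 20):
        p = rng.uniform(size=n)
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_bruteforce(p), atol=1e-12)
    # with ties
    p = np.array([0.01, 0.01, 0.5, 0.5, 0.9])
    np.testing.assert_allclose(benjamini_hochberg(p), _bh_bruteforce(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(size=15)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)


# ---------------------------------------------------------------------------
# clinical associations
# ---------------------------------------------------------------------------


def _clinical_frame():
    return pd.DataFrame(
        {
            "t_stage": ["4a", "3", "2", "1", "4a", "3", "2", "4a"],
            "n_stage": ["1", "0", "0", "0", "2b", "0", "0", "2b"],
            "stage": ["IV", "III", "II", "I", "IV", "III", "II", "IV"],
        },
        index=[f"p{i}" for i in range(8)],
    )


def test_clinical_logistic_reports_wald_p():
    rng = np.random.default_rng(0)
    counts = pd.Series(rng.integers(0, 200, 8), index=_clinical_frame().index)
    rep = clinical_associations(_clinical_frame(), counts)
    for name in ("t_stage_high", "node_positive", "stage_advanced"):
        assert name in rep["logistic"]
        fit = rep["logistic"][name]
        assert ("p" in fit) and (np.isnan(fit["p"]) or 0 <= fit["p"] <= 1)


def test_clinical_separation_flagged_not_raised():
    clin = _clinical_frame()
    # outcome perfectly separated by count
    counts = pd.Series([100, 1, 1, 1, 100, 1, 1, 100], index=clin.index, dtype=float)
    rep = clinical_associations(clin, counts)
    assert rep["logistic"]["node_positive"]["converged"] is False


def test_ttest_identical_groups_gives_t0_p1():
    clin = _clinical_frame()
    counts = pd.Series(np.arange(8.0), index=clin.index)
    emt = pd.Series([0.5] * 8, index=clin.index)
    rep = clinical_associations(clin, counts, emt_fraction=emt)
    assert rep["emt_by_node_ttest"]["t"] == 0.0
    assert rep["emt_by_node_ttest"]["p"] == 1.0


def test_anova_single_class_rejected():
    clin = _clinical_frame()
    counts = pd.Series(np.arange(8.0), index=clin.index)
    tc = pd.Series(["epithelial"] * 8, index=clin.index)
    with pytest.raises(ValueError, match="2 tumour classes"):
        clinical_associations(clin, counts, tumour_class=tc)


def test_null_wald_p_uniform():
    """Outcome independent of count by construction: Wald p uniform."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(150):
        n = 40
        counts = rng.integers(0, 200, n).astype(float)
        y = rng.integers(0, 2, n)
        clin = pd.DataFrame(
            {
                "t_stage": np.where(y == 1, "4a", "1"),
                "n_stage": "0",
                "stage": "II",
            },
            index=[f"p{i}" for i in range(n)],
        )
        rep = clinical_associations(clin, pd.Series(counts, index=clin.index))
        p = rep["logistic"]["t_stage_high"]["p"]
        if not np.isnan(p):
            pvals.append(p)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01
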