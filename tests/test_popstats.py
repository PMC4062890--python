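"""Frequency tables, pi diversity, permutation comparison, gradients, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from u6phylo.haplotree import CATEGORIES
from u6phylo.mtvar import HVR1, HaplotypeProfile, profile_distance
from u6phylo.popstats import (
    FrequencyTable,
    composition,
    counts_from_percentages,
    diversity_compare,
    gradient_correlation,
    load_table1,
    pca_scores,
    pi_diversity,
    u6_frequency,
)


def _profiles(token_sets):
    return [HaplotypeProfile.from_tokens(t, HVR1) for t in token_sets]


# -- frequency table ---------------------------------------------------------

def test_table1_worked_row():
    t = load_table1()
    assert t.u6_frequency("BRA") == 0.57
    row = t.row("BRA")
    assert int(row["u6_count"]) == 8
    assert int(row["U6a without 235"]) == 1
    assert int(row["U6a189 without 239"]) == 7
    comp = composition(row)
    assert comp["U6a without 235"] == 12.5
    assert comp["U6a189 without 239"] == 87.5


def test_table1_invariants_hold_for_every_region():
    t = load_table1()
    assert len(t) == 25
    cats = t.df[list(CATEGORIES)].sum(axis=1)
    assert (cats == t.df["u6_count"]).all()
    assert (t.df["u6_count"] <= t.df["sample_size"]).all()
    # reconstructed carrier counts reproduce the printed %U6 at 2 decimals
    for region in t.regions():
        row = t.row(region)
        printed = t.u6_frequency(region)
        assert u6_frequency(row) == printed


def test_canary_row_carrier_count():
    assert int(load_table1().row("CAN")["u6_count"]) == 168


def test_composition_rounds_to_about_100():
    t = load_table1()
    for region in t.regions():
        assert abs(composition(t.row(region)).sum() - 100.0) <= 0.2 + 1e-9


def test_composition_trivial_cases():
    row = pd.Series({"region": "X", "sample_size": 10, "u6_count": 4,
                     **{c: 0 for c in CATEGORIES}})
    row[CATEGORIES[0]] = 4
    assert composition(row)[CATEGORIES[0]] == 100.0
    for c in CATEGORIES[:4]:
        row[c] = 1
    assert composition(row)[CATEGORIES[1]] == 25.0
    row["u6_count"] = 0
    row[CATEGORIES[0]] = 0
    for c in CATEGORIES[1:4]:
        row[c] = 0
    with pytest.raises(ValueError):
        composition(row)


def test_u6_frequency_validation():
    row = pd.Series({"region": "X", "sample_size": 0, "u6_count": 0})
    with pytest.raises(ValueError):
        u6_frequency(row)


def test_counts_from_percentages_hits_total_exactly():
    assert counts_from_percentages([12.5, 87.5], 8) == [1, 7]
    assert counts_from_percentages([33.3, 33.3, 33.3], 3) == [1, 1, 1]
    assert sum(counts_from_percentages([11.4, 5.7, 5.7, 2.9, 65.7, 2.9, 5.7], 29)) == 29


def test_table_csv_round_trip(tmp_path):
    t = load_table1()
    path = tmp_path / "table.csv"
    t.to_csv(path)
    again = FrequencyTable.read_csv(path)
    pd.testing.assert_frame_equal(again.df, t.df)


# -- pi diversity ------------------------------------------------------------

def test_pi_identical_profiles_is_zero():
    est = pi_diversity(_profiles([["16189"]] * 3))
    assert est.pi == 0.0 and est.se == 0.0


def test_pi_three_profile_hand_computation():
    est = pi_diversity(_profiles([[], ["16189"], ["16189", "16311"]]))
    assert est.pi == pytest.approx(4 / 3)


def test_pi_matches_all_pairs_oracle():
    rng = np.random.default_rng(7)
    pool = [str(p) for p in range(16024, 16365, 10)]
    profs = _profiles(
        [list(rng.choice(pool, size=rng.integers(0, 6), replace=False)) for _ in range(12)]
    )
    est = pi_diversity(profs)
    pairs = list(itertools.combinations(profs, 2))
    oracle = sum(profile_distance(a, b) for a, b in pairs) / len(pairs)
    assert est.pi == pytest.approx(oracle, abs=1e-12)


def test_pi_requires_two_profiles():
    with pytest.raises(ValueError):
        pi_diversity(_profiles([["16189"]]))


# -- permutation comparison ---------------------------------------------------

def test_permutation_no_signal_gives_large_p():
    a = _profiles([[], ["16189"], ["16189", "16311"]] * 2)
    p = diversity_compare(a, list(a), n_perm=299, seed=1)
    assert p > 0.5


def test_permutation_extreme_case_gives_small_p():
    a = _profiles([["16189"]] * 8)  # zero diversity
    spread = [[], ["16051"], ["16086"], ["16111"], ["16129"], ["16163"],
              ["16172"], ["16219"]]
    b = _profiles(spread)  # maximal spread
    p = diversity_compare(a, b, n_perm=999, seed=2)
    assert p < 0.05


def test_permutation_is_reproducible_and_label_invariant():
    a = _profiles([[], ["16189"], ["16235"], ["16189", "16311"]])
    b = _profiles([["16051"], ["16051", "16086"], ["16111"], []])
    p1 = diversity_compare(a, b, n_perm=199, seed=42)
    p2 = diversity_compare(a, b, n_perm=199, seed=42)
    p3 = diversity_compare(b, a, n_perm=199, seed=42)
    assert p1 == p2 == p3


def test_permutation_warns_for_tiny_n_perm():
    a = _profiles([[], ["16189"]])
    b = _profiles([["16051"], []])
    with pytest.warns(UserWarning):
        diversity_compare(a, b, n_perm=50, seed=0)


# -- gradient correlation -----------------------------------------------------

def test_gradient_perfect_negative_slope():
    r, p = gradient_correlation([10, 8, 6, 4], [0, 10, 20, 30])
    assert r == pytest.approx(-1.0)
    assert p < 1e-6


def test_gradient_constant_vector_flagged():
    with pytest.warns(UserWarning):
        r, p = gradient_correlation([5, 5, 5], [0, 10, 20])
    assert np.isnan(r) and np.isnan(p)


def test_gradient_matches_textbook_formula():
    f = np.array([2.5, 1.1, 0.4, 0.2, 0.9])
    x = np.array([-9.0, -3.7, 12.5, 23.7, 14.4])
    r, _ = gradient_correlation(f, x)
    oracle = ((f - f.mean()) * (x - x.mean())).sum() / np.sqrt(
        ((f - f.mean()) ** 2).sum() * ((x - x.mean()) ** 2).sum()
    )
    assert r == pytest.approx(oracle, abs=1e-10)


# -- PCA -----------------------------------------------------------------------

def test_pca_separates_two_clusters():
    df = pd.DataFrame(
        [[10, 0, 5], [10, 0, 5], [0, 10, 1], [0, 10, 1]],
        index=["a1", "a2", "b1", "b2"], columns=["x", "y", "z"],
    )
    scores, loadings, ratio = pca_scores(df)
    pc1 = scores["PC1"]
    assert pc1["a1"] == pytest.approx(pc1["a2"], abs=1e-9)
    assert pc1["b1"] == pytest.approx(pc1["b2"], abs=1e-9)
    assert abs(pc1["a1"] - pc1["b1"]) > 1.0


def test_pca_matches_eigendecomposition_oracle():
    df = pd.DataFrame(
        [[1.0, 2.0, 0.5], [2.0, 1.0, 0.7], [3.0, 5.0, 0.2], [4.0, 3.0, 0.9]],
        columns=["c1", "c2", "c3"],
    )
    scores, loadings, _ = pca_scores(df)
    z = ((df - df.mean()) / df.std(ddof=0)).to_numpy()
    cov = z.T @ z / z.shape[0]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for i, col in enumerate(scores.columns):
        expected = z @ v[:, i]
        got = scores[col].to_numpy()
        agree = np.allclose(got, expected, atol=1e-8) or np.allclose(got, -expected, atol=1e-8)
        assert agree


def test_pca_drops_constant_columns_and_validates():
    df = pd.DataFrame([[1, 5.0], [1, 6.0], [1, 7.0]], columns=["const", "var"])
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            pca_scores(df)


def test_pca_of_survey_table_groups_canary_with_u6b1():
    """Populations dominated by the Canarian U6b1 subclade fall on the same
    PC1 side as the U6b1 loading (qualitative ordination check)."""
    t = load_table1()
    scores, loadings, _ = pca_scores(t.category_matrix())
    sign_u6b1 = np.sign(loadings.loc["PC1", "U6b1"])
    assert np.sign(scores.loc["CAN", "PC1"]) == sign_u6b1
    assert np.sign(scores.loc["HIS", "PC1"]) == sign_u6b1
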