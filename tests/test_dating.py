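"""rho/Saillard estimators, clock conversion, and the pedigree rate."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_mut_tree, rho_bruteforce, sigma_bruteforce
from u6phylo.dating import (
    ClockModel,
    MutNode,
    MutTree,
    age_from_rho,
    convert_rate,
    date_node,
    dating_table,
    generation_length,
    pedigree_rate,
    rho,
    saillard_sigma,
    sex_bias_halve,
)


def star(lengths, mults=None):
    root = MutNode(name="root")
    mults = mults or [1] * len(lengths)
    for i, (l, m) in enumerate(zip(lengths, mults)):
        root.add(MutNode(name=f"t{i}", length=l, multiplicity=m))
    return MutTree(root)


# -- closed-form examples ---------------------------------------------------

def test_rho_star_tree_mean():
    assert rho(star([1, 2, 3, 2])) == 2.0


def test_rho_zero_tree():
    assert rho(star([0, 0, 0])) == 0.0
    assert saillard_sigma(star([0, 0, 0])) == 0.0


def test_rho_two_tips():
    assert rho(star([1, 1])) == 1.0


def test_rho_weights_by_multiplicity():
    # 3 samples at distance 1, 1 sample at distance 5 -> (3*1 + 5)/4
    assert rho(star([1, 5], mults=[3, 1])) == 2.0


def test_sigma_star_unit_branches():
    assert saillard_sigma(star([1, 1, 1, 1])) == pytest.approx(0.5)
    assert saillard_sigma(star([1] * 9)) == pytest.approx(1 / 3)


def test_sigma_two_tip_hand_computed():
    assert saillard_sigma(star([2, 0])) == pytest.approx(math.sqrt(2) / 2)


def test_node_with_no_samples_errors():
    t = star([1, 1])
    lonely = MutNode(name="x")
    t.root.add(lonely)
    t._cache_n(t.root)
    with pytest.raises(ValueError):
        rho(t, lonely)


# -- oracle equivalence on random trees ------------------------------------

def test_rho_sigma_match_bruteforce_on_random_trees():
    rng = np.random.default_rng(20140519)
    for _ in range(300):
        t = random_mut_tree(rng)
        assert rho(t) == pytest.approx(rho_bruteforce(t), abs=1e-12)
        assert saillard_sigma(t) == pytest.approx(sigma_bruteforce(t), abs=1e-12)
        # also at a random internal node with sampled descendants
        internal = [n for n in t.walk() if n.children]
        node = internal[int(rng.integers(0, len(internal)))]
        assert rho(t, node) == pytest.approx(rho_bruteforce(t, node), abs=1e-12)
        assert saillard_sigma(t, node) == pytest.approx(sigma_bruteforce(t, node), abs=1e-12)


# -- clock ------------------------------------------------------------------

def test_age_from_rho_scales_point_and_error():
    est = age_from_rho(2.0, 0.5)
    assert est.age_years == pytest.approx(7248.0)
    assert est.age_se_years == pytest.approx(0.5 * 3624)
    assert age_from_rho(1.0, 0.0, ClockModel(1000)).age_years == 1000.0
    assert age_from_rho(0.0, 0.0).age_years == 0.0


def test_clock_must_be_positive():
    with pytest.raises(ValueError):
        ClockModel(0)


def test_date_node_and_table():
    t = star([1, 2, 3, 2])
    est = date_node(t)
    assert est.rho == 2.0 and est.age_years == pytest.approx(7248.0)
    lo, hi = est.interval()
    assert lo < est.age_years < hi
    table = dating_table(t)
    assert table.loc[0, "node"] == "root"
    assert table.loc[0, "rho"] == 2.0


# -- Newick round trip -------------------------------------------------------

def test_newick_parse_multiplicity_and_lengths():
    t = MutTree.from_newick("(A*3:1,B:5,(C:2,D:0)N1:1)root;")
    assert t.n_below(t.root) == 6
    assert rho(t) == pytest.approx((3 * 1 + 5 + 3 + 1) / 6)
    again = MutTree.from_newick(t.to_newick())
    assert rho(again) == rho(t)
    assert saillard_sigma(again) == saillard_sigma(t)


def test_newick_rejects_fractional_lengths():
    with pytest.raises(ValueError):
        MutTree.from_newick("(A:1.5,B:2)r;")


# -- pedigree rate -----------------------------------------------------------

def test_pedigree_point_estimate():
    est = pedigree_rate(1, 90)
    assert round(est.rate_per_transmission, 4) == 0.0111


def test_pedigree_cis_cover_the_estimate():
    est = pedigree_rate(1, 90)
    for lo, hi in (est.ci95_clopper_pearson, est.ci95_poisson):
        assert lo <= est.rate_per_transmission <= hi


def test_pedigree_clopper_pearson_against_exact_binomial_oracle():
    """CI bounds must invert the exact binomial tail probabilities."""
    est = pedigree_rate(1, 90)
    lo, hi = est.ci95_clopper_pearson
    # P(X >= 1 | lo) = 0.025 and P(X <= 1 | hi) = 0.025
    assert 1 - stats.binom.cdf(0, 90, lo) == pytest.approx(0.025, abs=1e-9)
    assert stats.binom.cdf(1, 90, hi) == pytest.approx(0.025, abs=1e-9)


def test_pedigree_zero_events_one_sided():
    est = pedigree_rate(0, 90)
    assert est.rate_per_transmission == 0.0
    assert est.ci95_clopper_pearson[0] == 0.0
    # one-sided 95% upper bound: 1 - (1-p)^90 = 0.95
    assert est.ci95_clopper_pearson[1] == pytest.approx(1 - 0.05 ** (1 / 90))


def test_pedigree_input_validation():
    with pytest.raises(ValueError):
        pedigree_rate(1, 0)
    with pytest.raises(ValueError):
        pedigree_rate(5, 4)


# -- unit conversions --------------------------------------------------------

@pytest.mark.parametrize("G, expected", [(20, 0.034), (25, 0.027), (30, 0.022)])
def test_convert_rate_per_site_per_my(G, expected):
    assert round(convert_rate(1 / 90, 16569, G), 3) == expected


def test_convert_rate_linear_and_commutes_with_halving():
    assert convert_rate(0.0, 16569, 25) == 0.0
    r = 1 / 90
    assert convert_rate(2 * r, 16569, 25) == pytest.approx(2 * convert_rate(r, 16569, 25))
    assert sex_bias_halve(convert_rate(r, 16569, 20)) == pytest.approx(
        convert_rate(sex_bias_halve(r), 16569, 20)
    )


def test_sex_bias_halving():
    assert sex_bias_halve(0.034) == 0.017
    assert sex_bias_halve(0.0) == 0.0
    assert sex_bias_halve(1.0) == 0.5


def test_generation_length():
    assert generation_length(1625, 2000, 15) == 25.0
    assert generation_length(0, 100, 4) == 25.0
    assert generation_length(1625, 2000, 1) == 375.0
    with pytest.raises(ValueError):
        generation_length(2000, 1625, 15)
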