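"""Closed-form expectations vs the independent single-locus enumeration oracle."""

import numpy as np
import pytest

import landracegp as lg
from landracegp.traits import TraitArchitecture

from oracles import (
    gc_s1_dose_variance,
    ls_dist,
    pp_values,
    single_locus_cells,
)

P_GRID = np.round(np.arange(0.0, 1.01, 0.1), 10)


def one_locus_trait(p, a, delta=0.0, d12=0.0, d2x=None, td=0.0, tester=1, intercept=0.0):
    private = p == 0.0
    if d2x is None:
        d2x = 0.0 if private else d12
    return TraitArchitecture(
        qtl=np.array([0]),
        a=np.array([a]),
        delta=np.array([delta if private else 0.0]),
        d12=np.array([0.0 if private else d12]),
        d1x=np.array([0.0]),
        d2x=np.array([d2x]),
        private=np.array([private]),
        tester=np.array([tester], dtype=np.uint8),
        tester_d=np.array([td]),
        intercept=intercept,
    )


# --- the module's core test: every coefficient-table cell vs enumeration ----

CONFIGS = [
    # (a, delta, d12, td, tester) at non-private loci (delta forced 0)
    (1.0, 0.0, 0.0, 0.0, 1),
    (2.0, 0.0, 0.0, 0.0, 0),
    (-1.3, 0.0, 0.0, 0.7, 1),
    (0.8, 0.0, 0.0, -0.4, 0),
]


@pytest.mark.parametrize("a,delta,d12,td,tester", CONFIGS)
@pytest.mark.parametrize("p", P_GRID[P_GRID > 0])
def test_expectation_cells_match_enumeration_additive(p, a, delta, d12, td, tester):
    """All mean and variance cells agree with exact enumeration (additive PP,
    arbitrary tester dominance for TP) at every allele frequency."""
    trait = one_locus_trait(p, a, delta, d12, td=td, tester=tester, intercept=0.3)
    rep = lg.expected_population_stats(trait, np.array([p]))
    oracle = single_locus_cells(p, a, 0.0, d12, td=td, tester=tester, intercept=0.3)
    for level in ("PP", "TP"):
        for popname in ("LS", "DH", "GC_S1_2", "GC_S1_INF", "CAPTURE"):
            row = rep.row(popname, level)
            exp = oracle[level][popname]
            assert row["mean"] == pytest.approx(exp["mean"], abs=1e-12)
            assert row["primary"] == pytest.approx(exp["primary"], abs=1e-12)
            assert row["within_family"] == pytest.approx(exp["within"], abs=1e-12)
            assert row["total"] == pytest.approx(exp["total"], abs=1e-12)


@pytest.mark.parametrize("p", P_GRID[P_GRID > 0])
@pytest.mark.parametrize("d12", [0.5, -0.8, 1.7])
def test_expectation_means_match_enumeration_with_dominance(p, d12):
    """Mean cells stay exact with dominance; inbred-generation variances too.

    (The variance cells of the table are additive components, so segregating
    generations additionally carry dominance variance not listed there.)"""
    a = 1.1
    trait = one_locus_trait(p, a, d12=d12)
    rep = lg.expected_population_stats(trait, np.array([p]))
    oracle = single_locus_cells(p, a, 0.0, d12)
    for popname in ("LS", "DH", "GC_S1_2", "GC_S1_INF", "CAPTURE"):
        assert rep.row(popname, "PP")["mean"] == pytest.approx(
            oracle["PP"][popname]["mean"], abs=1e-12
        )
    # DH carry no heterozygotes: all DH variance cells stay exact
    assert rep.row("DH", "PP")["total"] == pytest.approx(oracle["PP"]["DH"]["total"], abs=1e-12)


@pytest.mark.parametrize("delta", [0.0, 1.5, -2.0])
@pytest.mark.parametrize("d2x", [0.0, 0.9])
def test_private_locus_cells_match_enumeration(delta, d2x):
    """At capture-private loci (p=0) the capture-specific effects Delta and
    d2x drive means; additive variance cells are exact when d2x=0."""
    p, a = 0.0, 1.2
    trait = one_locus_trait(p, a, delta=delta, d2x=d2x, intercept=-0.5)
    rep = lg.expected_population_stats(trait, np.array([p]))
    oracle = single_locus_cells(p, a, delta, d2x, intercept=-0.5)
    for popname in ("LS", "DH", "GC_S1_2", "GC_S1_INF", "CAPTURE"):
        assert rep.row(popname, "PP")["mean"] == pytest.approx(
            oracle["PP"][popname]["mean"], abs=1e-12
        )
        if d2x == 0.0:
            for cell, key in (("primary", "primary"), ("within_family", "within"), ("total", "total")):
                assert rep.row(popname, "PP")[cell] == pytest.approx(
                    oracle["PP"][popname][key], abs=1e-12
                )


def test_multi_locus_cells_sum_over_qtl():
    """With unlinked QTL every cell is the per-locus sum (oracle summed)."""
    ps = np.array([0.2, 0.5, 0.0, 0.8])
    a = np.array([1.0, -0.7, 1.5, 0.4])
    delta = np.array([0.0, 0.0, 2.0, 0.0])
    d2x = np.zeros(4)  # additive: the table's variance cells are additive components
    trait = TraitArchitecture(
        qtl=np.arange(4), a=a, delta=delta, d12=np.zeros(4), d1x=np.zeros(4),
        d2x=d2x, private=ps == 0, tester=np.array([1, 0, 1, 1], dtype=np.uint8),
        tester_d=np.array([0.3, 0.0, -0.2, 0.1]), intercept=2.0,
    )
    rep = lg.expected_population_stats(trait, ps)
    for level in ("PP", "TP"):
        for popname in ("LS", "DH", "GC_S1_2", "GC_S1_INF"):
            cells = [
                single_locus_cells(ps[j], a[j], delta[j], d2x[j] if ps[j] == 0 else 0.0,
                                   td=trait.tester_d[j], tester=int(trait.tester[j]))[level][popname]
                for j in range(4)
            ]
            row = rep.row(popname, level)
            # dominance is zero at non-private loci here, so variances are exact
            assert row["mean"] == pytest.approx(2.0 + sum(c["mean"] for c in cells), abs=1e-10)
            assert row["total"] == pytest.approx(sum(c["total"] for c in cells), abs=1e-10)


# --- single-locus genotype values -------------------------------------------

def test_pp_parameterization_reproduces_landrace_moments():
    """With value(+a) for A1A1 and -a for A2A2, the LS mean is (p-(1-p))a and
    the LS variance 2p(1-p)a^2 by direct enumeration of the three genotypes."""
    p, a = 0.3, 2.0
    trait = one_locus_trait(p, a)
    vals = lg.genotypic_value_pp(np.array([[0], [1], [2]]), trait)
    dist = ls_dist(p)
    mean = dist @ vals
    var = dist @ vals**2 - mean**2
    assert mean == pytest.approx((p - (1 - p)) * a)
    assert var == pytest.approx(2 * p * (1 - p) * a**2)
    np.testing.assert_allclose(vals, pp_values(a, 0.0, 0.0))


def test_heterozygote_additive_midpoint_and_dominance():
    trait_add = one_locus_trait(0.5, 1.4)
    v = lg.genotypic_value_pp(np.array([[0], [1], [2]]), trait_add)
    assert v[1] == pytest.approx((v[0] + v[2]) / 2)
    trait_dom = one_locus_trait(0.5, 1.4, d12=0.6)
    v = lg.genotypic_value_pp(np.array([[0], [1], [2]]), trait_dom)
    assert v[1] == pytest.approx((v[0] + v[2]) / 2 + 0.6)


def test_tp_linear_in_dh_dose_and_half_contrast():
    """TP of DH entries is linear in allele count; with the tester equal to
    the capture line and no dominance, the TP contrast is half the PP one."""
    trait = one_locus_trait(0.4, 1.0, tester=1)
    doses = np.array([[0], [1], [2]])
    tp = lg.genotypic_value_tp(doses, trait)
    assert np.diff(tp, 2)[0] == pytest.approx(0.0, abs=1e-12)  # linear
    pp = lg.genotypic_value_pp(doses, trait)
    assert (tp[2] - tp[0]) == pytest.approx((pp[2] - pp[0]) / 2)


def test_tp_of_heterozygote_is_gamete_mean():
    trait = one_locus_trait(0.4, 1.0, td=0.8, tester=0)
    tp = lg.genotypic_value_tp(np.array([[0], [1], [2]]), trait)
    assert tp[1] == pytest.approx((tp[0] + tp[2]) / 2)


# --- molecular variance, thresholds, frequency shifts ------------------------

def test_molecular_variance_formulas():
    p = np.array([0.0, 1 / 3, 0.5, 1.0])
    np.testing.assert_allclose(lg.molecular_variance_expected("LS", p), 2 * p * (1 - p))
    np.testing.assert_allclose(lg.molecular_variance_expected("DH", p), 2 * p * (1 - p))
    gc = lg.molecular_variance_expected("GC_S1", p)
    np.testing.assert_allclose(gc, 0.5 * (1 + p) * (1 - p))
    assert gc[0] == pytest.approx(0.5)
    assert gc[-1] == 0.0
    # the two formulas cross exactly at p = 1/3 (value 4/9)
    assert gc[1] == pytest.approx(4 / 9)
    assert lg.molecular_variance_expected("LS", np.array([1 / 3]))[0] == pytest.approx(4 / 9)
    # GC formula equals 2f(1-f) at the shifted frequency f=(p+1)/2
    f = lg.expected_gc_frequency(p)
    np.testing.assert_allclose(gc, 2 * f * (1 - f))
    with pytest.raises(ValueError):
        lg.molecular_variance_expected("LS", np.array([1.5]))
    with pytest.raises(ValueError):
        lg.molecular_variance_expected("NOPE", p[:1])


def test_variance_thresholds_solved_numerically():
    p_mol, p_gen = lg.variance_thresholds()
    assert p_mol == pytest.approx(1 / 3, abs=1e-9)
    assert p_gen == pytest.approx(1 / 6, abs=1e-9)


def test_gc_s1_dose_variance_enumeration_matches_closed_form():
    """Between-family GC-S1 allele-count variance is (1-p)(1/2+p)."""
    for p in P_GRID:
        assert gc_s1_dose_variance(p) == pytest.approx((1 - p) * (0.5 + p), abs=1e-12)


def test_random_dh_capture_average_recovers_landrace_variance():
    """Averaging sigma2_A* over a capture allele drawn with probability p
    (allele A1) / 1-p (allele A2) gives back sigma2_A."""
    for p in P_GRID[1:-1]:
        a = 1.7
        s2a = 2 * p * (1 - p) * a**2
        # capture carries A1: coded orientation unchanged
        s_a1 = 2 * ((1 - p) * a) ** 2
        # capture carries A2: coded orientation flips (p -> 1-p, a -> -a)
        s_a2 = 2 * (p * a) ** 2
        assert p * s_a1 + (1 - p) * s_a2 == pytest.approx(s2a, abs=1e-12)


def test_expected_gc_frequency_properties():
    p = np.linspace(0, 1, 11)
    f = lg.expected_gc_frequency(p)
    assert f[0] == pytest.approx(0.5)
    assert f[-1] == pytest.approx(1.0)
    assert np.all(np.diff(f) > 0)


# --- [d] and [d*] from population means --------------------------------------

def test_inbreeding_contribution_estimates_from_expected_means():
    """[d] = mean(LS)-mean(DH) and [d*] = 4(mean(GC)-(mean(DH)+mean(FV2))/2)
    recover the cumulative dominance sums exactly from the closed forms."""
    ps = np.array([0.3, 0.6, 0.0])
    trait = TraitArchitecture(
        qtl=np.arange(3), a=np.array([1.0, -0.5, 0.9]),
        delta=np.array([0.0, 0.0, 1.1]), d12=np.array([0.4, 0.7, 0.0]),
        d1x=np.zeros(3), d2x=np.array([0.4, 0.7, 0.25]), private=ps == 0,
        intercept=5.0,
    )
    rep = lg.expected_population_stats(trait, ps)
    d_hat, dstar_hat = lg.estimate_inbreeding_contributions(
        rep.row("LS", "PP")["mean"], rep.row("DH", "PP")["mean"],
        rep.row("GC_S1_2", "PP")["mean"], rep.row("CAPTURE", "PP")["mean"],
    )
    d_true = float(np.sum(2 * ps * (1 - ps) * trait.d12))
    dstar_true = float(np.sum((1 - ps) * trait.d2x))
    assert d_hat == pytest.approx(d_true, abs=1e-12)
    assert dstar_hat == pytest.approx(dstar_true, abs=1e-12)
    # purely additive trait: both estimates vanish
    add = TraitArchitecture(
        qtl=np.arange(3), a=trait.a, delta=trait.delta, d12=np.zeros(3),
        d1x=np.zeros(3), d2x=np.zeros(3), private=ps == 0,
    )
    rep_add = lg.expected_population_stats(add, ps)
    d0, ds0 = lg.estimate_inbreeding_contributions(
        rep_add.row("LS", "PP")["mean"], rep_add.row("DH", "PP")["mean"],
        rep_add.row("GC_S1_2", "PP")["mean"], rep_add.row("CAPTURE", "PP")["mean"],
    )
    assert d0 == pytest.approx(0.0, abs=1e-12)
    assert ds0 == pytest.approx(0.0, abs=1e-12)
    # and the GC mean then lies exactly between DH and the capture line
    assert rep_add.row("GC_S1_2", "PP")["mean"] == pytest.approx(
        (rep_add.row("DH", "PP")["mean"] + rep_add.row("CAPTURE", "PP")["mean"]) / 2
    )


# --- architecture construction ------------------------------------------------

def test_assign_trait_constraints_and_determinism(gmap_small, landrace):
    pool, capture = landrace
    t1 = lg.assign_trait(gmap_small, pool.p, 40, seed=5, private_loci=capture.private_loci,
                         dominance_spec={"d12": ("prop", 0.5), "d2x_private": 0.3})
    t2 = lg.assign_trait(gmap_small, pool.p, 40, seed=5, private_loci=capture.private_loci,
                         dominance_spec={"d12": ("prop", 0.5), "d2x_private": 0.3})
    np.testing.assert_array_equal(t1.qtl, t2.qtl)
    np.testing.assert_allclose(t1.a, t2.a)
    nonpriv = ~t1.private
    assert np.all(t1.delta[nonpriv] == 0)
    np.testing.assert_allclose(t1.d2x[nonpriv], t1.d12[nonpriv])
    assert np.all(t1.d12[t1.private] == 0)
    # purely additive by default
    t3 = lg.assign_trait(gmap_small, pool.p, 40, seed=6)
    assert np.all(t3.d12 == 0) and np.all(t3.d2x == 0)
    with pytest.raises(ValueError):
        lg.assign_trait(gmap_small, pool.p, 0, seed=1)


def test_true_entry_values_analytic_matches_simulated_family_mean(landrace):
    pool, capture = landrace
    import landracegp.populations as pops

    _, s1 = lg.derive_gc(pool, capture, 30, rng=21)
    trait = lg.assign_trait(pool.gmap, pool.p, 30, seed=22, private_loci=capture.private_loci,
                            dominance_spec={"d12": 0.4, "d2x_private": 0.2})
    analytic = lg.true_entry_values(s1, trait, level="PP")
    simulated = lg.true_entry_values(s1, trait, level="PP", s2_family_size=400, rng=23)
    assert np.corrcoef(analytic, simulated)[0, 1] > 0.99
    np.testing.assert_allclose(analytic, simulated, atol=4 * np.std(analytic - simulated) + 1e-9)
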