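"""Independent single-locus enumeration oracles.

These enumerate exact genotype distributions per population from first
principles (HWE, gamete doubling, the selfing transition matrix) and
compute means/variances directly from the distributions.  They share no
code with the package's closed-form coefficient table.
"""

import numpy as np

DOSES = np.array([0.0, 1.0, 2.0])

# selfing transition matrix: row = parent dose, column = offspring dose
SELF_T = np.array([
    [1.0, 0.0, 0.0],
    [0.25, 0.5, 0.25],
    [0.0, 0.0, 1.0],
])
# limit of repeated selfing: heterozygotes fix to either homozygote
FIX_INF = np.array([
    [1.0, 0.0, 0.0],
    [0.5, 0.0, 0.5],
    [0.0, 0.0, 1.0],
])


def pp_values(a, delta, d_het):
    """Genotypic value by dose (0, 1, 2) of the capture allele."""
    return np.array([-a, delta / 2.0 + d_het, a + delta])


def tp_values(a, delta, td, tester):
    """Expected testcross value of an entry by entry dose, via hybrid doses.

    A testcross plant carries the tester allele plus one entry gamete drawn
    uniformly; hybrid heterozygotes take the tester-interaction dominance td.
    """
    def v_hyb(h):
        return (h - 1) * a + (h / 2.0) * delta + (1.0 if h == 1 else 0.0) * td

    w0 = v_hyb(tester)        # testcross value of a 0-gamete
    w1 = v_hyb(tester + 1)    # testcross value of a 1-gamete
    return np.array([w0, (w0 + w1) / 2.0, w1])


def ls_dist(p):
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def dh_dist(p):
    return np.array([1 - p, 0.0, p])


def gc_s1_dist(p):
    """One selfed offspring of an S0 = (capture gamete, Bernoulli(p) gamete)."""
    s0 = np.array([0.0, 1 - p, p])  # S0 dose distribution (1 + landrace allele)
    return s0 @ SELF_T


def dist_moments(dist, values):
    mean = float(dist @ values)
    var = float(dist @ values**2 - mean**2)
    return mean, var


def family_moments(parent_dist, transition, values):
    """(mean, primary (between-family), within-family, total) variance.

    Entries are families founded by a parent drawn from ``parent_dist``;
    family members are distributed per ``transition`` row of the parent.
    """
    cond_mean = transition @ values
    cond_var = transition @ values**2 - cond_mean**2
    mean = float(parent_dist @ cond_mean)
    primary = float(parent_dist @ cond_mean**2 - mean**2)
    within = float(parent_dist @ cond_var)
    return mean, primary, within, primary + within


def single_locus_cells(p, a, delta, d_het, td=0.0, tester=1, intercept=0.0):
    """Every mean/variance cell for one locus, both performance levels."""
    vpp = pp_values(a, delta, d_het) + intercept
    vtp = tp_values(a, delta, td, tester) + intercept
    out = {}
    for level, v in (("PP", vpp), ("TP", vtp)):
        m_ls, v_ls = dist_moments(ls_dist(p), v)
        m_dh, v_dh = dist_moments(dh_dist(p), v)
        s1 = gc_s1_dist(p)
        m_12, pr_12, wi_12, to_12 = family_moments(s1, SELF_T, v)
        m_inf, pr_inf, wi_inf, to_inf = family_moments(s1, FIX_INF, v)
        out[level] = {
            "LS": {"mean": m_ls, "primary": v_ls, "within": 0.0, "total": v_ls},
            "DH": {"mean": m_dh, "primary": v_dh, "within": 0.0, "total": v_dh},
            "GC_S1_2": {"mean": m_12, "primary": pr_12, "within": wi_12, "total": to_12},
            "GC_S1_INF": {"mean": m_inf, "primary": pr_inf, "within": wi_inf, "total": to_inf},
            "CAPTURE": {"mean": float(v[2]), "primary": 0.0, "within": 0.0, "total": 0.0},
        }
    return out


def gc_s1_dose_variance(p):
    """Between-family variance of GC-S1 allele counts (enumeration)."""
    return dist_moments(gc_s1_dist(p), DOSES)[1]
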