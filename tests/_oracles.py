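"""Independent brute-force oracles used by the test suite.

Everything here recomputes expectations from first principles with
exact rational arithmetic (enumeration over meiotic draws, direct
hypergeometric sums) and deliberately shares no code with the package.
"""

import itertools
import math
from fractions import Fraction

HALF = Fraction(1, 2)


def enumerate_meioses(phase, rs):
    """Pre-selection gamete distribution by enumerating every meiotic draw.

    phase: pair of allele tuples; rs: adjacent recombination fractions
    (Fractions for exactness).  Returns {haplotype: probability}.
    """
    n = len(phase[0])
    out = {}
    for bits in itertools.product((0, 1), repeat=n):
        p = HALF
        for i in range(1, n):
            r = Fraction(rs[i - 1])
            p *= r if bits[i] != bits[i - 1] else 1 - r
        hap = tuple(phase[b][i] for i, b in enumerate(bits))
        out[hap] = out.get(hap, Fraction(0)) + p
    return {h: p for h, p in out.items() if p}


def select_gametes(gametes, rules, sex):
    """Apply (pattern, sex, penetrance) rules; returns unnormalised dict."""
    out = {}
    for hap, p in gametes.items():
        v = Fraction(1)
        for pattern, rule_sex, pen in rules:
            applies = rule_sex == "both" or rule_sex == sex
            hits = all(q is None or q == a for q, a in zip(pattern, hap))
            if applies and hits:
                v *= 1 - Fraction(pen)
        if v:
            out[hap] = p * v
    return out


def offspring_oracle(mother_phase, father_phase, rs, rules):
    """Exact offspring class distribution over unphased states."""
    eggs = select_gametes(enumerate_meioses(mother_phase, rs), rules, "female")
    sperm = select_gametes(enumerate_meioses(father_phase, rs), rules, "male")
    z_e, z_s = sum(eggs.values()), sum(sperm.values())
    out = {}
    for he, pe in eggs.items():
        for hs, ps in sperm.items():
            states = tuple(a + b for a, b in zip(he, hs))
            out[states] = out.get(states, Fraction(0)) + (pe / z_e) * (ps / z_s)
    return out


def pollen_fertility_oracle(phase, rs, rules):
    """Surviving fraction of male gametes."""
    gametes = enumerate_meioses(phase, rs)
    kept = select_gametes(gametes, rules, "male")
    return sum(kept.values())


def fisher_tail_oracle(a, b, c, d, alternative):
    """Exact Fisher p by direct enumeration of the hypergeometric support."""
    n = a + b + c + d
    k_col, n_row = a + c, a + b
    lo, hi = max(0, n_row - (b + d)), min(k_col, n_row)
    denom = math.comb(n, n_row)
    pmf = {x: Fraction(math.comb(k_col, x) * math.comb(n - k_col, n_row - x),
                       denom)
           for x in range(lo, hi + 1)}
    if alternative == "greater":
        p = sum(q for x, q in pmf.items() if x >= a)
    elif alternative == "less":
        p = sum(q for x, q in pmf.items() if x <= a)
    else:  # two-sided, minimum-likelihood convention
        p = sum(q for q in pmf.values() if q <= pmf[a])
    return min(p, Fraction(1))
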