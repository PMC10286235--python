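"""Independent brute-force oracles, written directly from the defining
formulas and sharing no code with the package implementation."""

from fractions import Fraction
from math import comb, factorial


def brute_window_fst(ref_i, alt_i, ref_j, alt_j, n_i, n_j):
    """Ratio-of-sums window FST from scalar arithmetic on each SNP.

    Q1 per pool: 1 - (n/(n-1)) * (c/(c-1)) * 2*p*(1-p) with p the read
    alt-frequency; Q2 = p_i*p_j + (1-p_i)*(1-p_j); window value is
    sum(mean(Q1_i, Q1_j) - Q2) / sum(1 - Q2) over SNPs with depth >= 2 in
    both pools.  Returns None when no SNP is usable or the denominator is 0.
    """
    num = 0.0
    den = 0.0
    any_usable = False
    for ri, ai, rj, aj in zip(ref_i, alt_i, ref_j, alt_j):
        ci = ri + ai
        cj = rj + aj
        if ci < 2 or cj < 2:
            continue
        any_usable = True
        pi = ai / ci
        pj = aj / cj
        q1i = 1.0 - (n_i / (n_i - 1.0)) * (ci / (ci - 1.0)) * 2.0 * pi * (1.0 - pi)
        q1j = 1.0 - (n_j / (n_j - 1.0)) * (cj / (cj - 1.0)) * 2.0 * pj * (1.0 - pj)
        q2 = pi * pj + (1.0 - pi) * (1.0 - pj)
        num += (q1i + q1j) / 2.0 - q2
        den += 1.0 - q2
    if not any_usable or den == 0.0:
        return None
    return num / den


def brute_ehh(alleles, positions, core, carrier_cols, target):
    """EHH at marker ``target`` by exhaustive pair enumeration.

    Counts pairs of carriers identical at every marker between the core and
    the target inclusive; divides by the number of carrier pairs.
    """
    lo, hi = min(core, target), max(core, target)
    n_c = len(carrier_cols)
    if n_c < 2:
        raise ValueError("need two carriers")
    identical = 0
    for x in range(n_c):
        for y in range(x + 1, n_c):
            a, b = carrier_cols[x], carrier_cols[y]
            if all(alleles[m][a] == alleles[m][b] for m in range(lo, hi + 1)):
                identical += 1
    return identical / (n_c * (n_c - 1) / 2)


def brute_hwe_p(n_AA, n_Aa, n_aa):
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = (
            2**h * factorial(n)
            // (factorial(hom_rare) * factorial(h) * factorial(hom_common))
        )
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    p = sum(Fraction(w, total) for w in weights.values() if w <= w_obs)
    return float(p)


def brute_hypergeom_p(universe_n, term_k, query_n, overlap):
    """Upper-tail hypergeometric tail by direct summation of binomials."""
    total = comb(universe_n, query_n)
    p = Fraction(0)
    for x in range(overlap, min(term_k, query_n) + 1):
        p += Fraction(comb(term_k, x) * comb(universe_n - term_k, query_n - x), total)
    return float(p)
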