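"""Independent brute-force oracle for the Weir–Cockerham variance components.

Written directly from the per-locus estimator definition using exact
rational arithmetic (fractions.Fraction), deliberately sharing no code with
the package implementation. Inputs are raw genotype-count triples
(n_short_hom, n_het, n_long_hom) per population.
"""

from fractions import Fraction


def wc_theta_oracle(genotype_counts):
    """Exact theta from per-population genotype counts; None if monomorphic."""
    r = len(genotype_counts)
    n = [Fraction(sum(c)) for c in genotype_counts]
    p = [
        (Fraction(c[1]) + 2 * Fraction(c[2])) / (2 * ni)
        for c, ni in zip(genotype_counts, n)
    ]
    h = [Fraction(c[1]) / ni for c, ni in zip(genotype_counts, n)]

    n_tot = sum(n)
    n_bar = n_tot / r
    n_c = (n_tot - sum(ni * ni for ni in n) / n_tot) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_tot
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_tot

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - Fraction(r - 1, r) * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2

    denom = a + b + c
    if denom == 0:
        return None
    return a / denom
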