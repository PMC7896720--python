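"""Independent, deliberately naive oracles used to cross-check the
vectorized implementations.

Each function is a literal scalar transcription of the published
formula (or an exact enumeration), written without reference to the
package internals.
"""

from __future__ import annotations

import math
from fractions import Fraction


def wc_components_oracle(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c for two samples, scalar arithmetic."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pooled_fis_oracle(n, p, h):
    """Single-sample F_IS = 1 - c/(b+c) with the r=1 WC formulas."""
    b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
    c = h / 2
    if b + c == 0:
        return float("nan")
    return 1 - c / (b + c)


def hdplot_d_oracle(het_depths):
    """HDplot deviation from a list of (reads_a, reads_b) heterozygote pairs."""
    total = sum(a + b for a, b in het_depths)
    sum_a = sum(a for a, _ in het_depths)
    if total == 0:
        return float("nan")
    return (sum_a - total / 2) / math.sqrt(total / 4)


def fisher_exact_oracle(table):
    """Two-sided Fisher exact p by exact rational enumeration.

    Sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's
    (small relative guard for float-free tie handling is unnecessary:
    Fractions are exact).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(first cell = x), exact
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)
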