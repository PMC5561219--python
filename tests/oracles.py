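"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is transcribed directly from the published definitions
(Weir & Cockerham 1984 variance components; Tajima 1989 constants; haplotype
homozygosity by literal string counting) using plain Python loops, sharing no
code with the package.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from math import isnan, sqrt


def wc_site_components(genosA, genosB):
    """Weir & Cockerham (1984) a, b, c for one biallelic site, two populations.

    ``genosA``/``genosB``: lists of (allele1, allele2) with alleles in
    {0, 1} or None for missing (an individual with any missing allele is
    excluded). Returns (a, b, c) or None if undefined.
    """
    pops = []
    for genos in (genosA, genosB):
        called = [g for g in genos if g[0] is not None and g[1] is not None]
        n_i = len(called)
        if n_i == 0:
            return None
        p_i = sum(g[0] + g[1] for g in called) / (2 * n_i)
        h_i = sum(1 for g in called if g[0] != g[1]) / n_i
        pops.append((n_i, p_i, h_i))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    if nbar <= 1:
        return None
    nsum = sum(n for n, _, _ in pops)
    nc = (nsum - sum(n * n for n, _, _ in pops) / nsum) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / nsum
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / nsum
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_windowed_fst(genosA, genosB):
    """Ratio-of-sums Fst over sites; genos*: per-site lists as above."""
    num = den = 0.0
    any_defined = False
    for ga, gb in zip(genosA, genosB):
        comp = wc_site_components(ga, gb)
        if comp is None:
            continue
        any_defined = True
        a, b, c = comp
        num += a
        den += a + b + c
    if not any_defined or den == 0.0:
        return float("nan")
    return num / den


def h12_bruteforce(haplotypes):
    """H12 from a list of haplotype tuples (no missing): literal counting."""
    counts = sorted(Counter(tuple(h) for h in haplotypes).values(), reverse=True)
    total = sum(counts)
    freqs = [c / total for c in counts]
    p1 = freqs[0]
    p2 = freqs[1] if len(freqs) > 1 else 0.0
    return (p1 + p2) ** 2 + sum(p * p for p in freqs[2:])


def tajimas_d_bruteforce(sequences):
    """Tajima (1989) D from complete-data sequences (lists of 0/1 alleles).

    pi by literal pairwise-difference enumeration; constants from the
    published definitions.
    """
    n = len(sequences)
    L = len(sequences[0])
    S = 0
    for j in range(L):
        col = {seq[j] for seq in sequences}
        if len(col) > 1:
            S += 1
    if S == 0 or n < 4:
        return float("nan")
    pairs = 0
    diffs = 0
    for x, y in combinations(sequences, 2):
        pairs += 1
        diffs += sum(1 for a, b in zip(x, y) if a != b)
    pi = diffs / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    d = (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))
    assert not isnan(d)
    return d


def chi2_2x2(table):
    """Pearson chi-squared for a 2x2 table, no continuity correction."""
    (a, b), (c, d) = table
    n = a + b + c + d
    chi2 = 0.0
    for i, row_sum in enumerate((a + b, c + d)):
        for j, col_sum in enumerate((a + c, b + d)):
            obs = table[i][j]
            exp = row_sum * col_sum / n
            chi2 += (obs - exp) ** 2 / exp
    return chi2
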