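"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle is an
exact integer enumeration of the hypergeometric null, and the mixture oracle
counts allele copies over an explicit integer population of cells.
"""
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with integer weights."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(kmin, kmax + 1)]
    w_obs = comb(r1, a) * comb(n - r1, c1 - a)
    return sum(w for w in weights if w <= w_obs) / comb(n, c1)


def mixture_allele_fraction(populations, n_cells: int = 10_000) -> float:
    """Allele fraction by explicit counting over an integer cell population.

    ``populations`` is a list of (fraction, alt_copies, total_copies); each
    population contributes round(fraction * n_cells) cells.
    """
    counts = [round(frac * n_cells) for frac, _, _ in populations]
    alt = sum(n * a for n, (_, a, _) in zip(counts, populations))
    total = sum(n * t for n, (_, _, t) in zip(counts, populations))
    return alt / total
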