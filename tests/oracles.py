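"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: tail probabilities
by direct enumeration with exact integer combinatorics, adapter search
by a naive sliding scan, correlation by the textbook moment formula.
"""

from math import comb, sqrt


def hypergeom_tail_enum(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) by exact enumeration over the support."""
    total = comb(population, draws)
    upper = min(successes, draws)
    return sum(
        comb(successes, x) * comb(population - successes, draws - x)
        for x in range(max(k, 0), upper + 1)
    ) / total


def binom_tail_enum(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of the pmf."""
    return sum(comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(max(k, 0), n + 1))


def pearson_textbook(xs, ys) -> float:
    """Covariance over the product of standard deviations, from raw moments."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    sx = sqrt(sum((x - mx) ** 2 for x in xs) / n)
    sy = sqrt(sum((y - my) ** 2 for y in ys) / n)
    return cov / (sx * sy)


def adapter_scan_naive(read: str, core: str, max_mismatches: int, min_core_prefix: int):
    """Leftmost core occurrence (Hamming, substitutions only); a core
    truncated by the read end counts if >= min_core_prefix bases remain.
    Returns (start, mismatches) or None."""
    for start in range(len(read)):
        window = read[start : start + len(core)]
        if len(window) < min(len(core), min_core_prefix):
            break
        mm = sum(a != b for a, b in zip(window, core))
        if mm <= max_mismatches:
            return start, mm
    return None
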