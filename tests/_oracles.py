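"""Independent brute-force oracles used to check the package's statistics.

These are deliberately naive: exact integer arithmetic and full enumeration,
never sharing code with the implementation they verify.
"""

from math import comb


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by full hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the point
    probabilities no larger than the observed one, using exact integer
    arithmetic until the final division.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    a_min = max(0, col1 - (n - row1))
    a_max = min(row1, col1)
    weights = {
        x: comb(row1, x) * comb(n - row1, col1 - x)
        for x in range(a_min, a_max + 1)
    }
    observed = weights[a]
    return sum(w for w in weights.values() if w <= observed) / denom


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1))
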