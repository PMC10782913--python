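"""Independent small-scale oracles used to check the numeric implementations."""

from fractions import Fraction
from math import factorial


def fisher_point_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Hypergeometric point probability of a 2x2 table, in exact rationals."""
    n = a + b + c + d
    return Fraction(
        factorial(a + b) * factorial(c + d) * factorial(a + c) * factorial(b + d),
        factorial(a) * factorial(b) * factorial(c) * factorial(d) * factorial(n),
    )


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p: exact sum of point probabilities <= the observed."""
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    obs = fisher_point_exact(a, b, c, d)
    total = Fraction(0)
    for aa in range(lo, hi + 1):
        p = fisher_point_exact(aa, row1 - aa, col1 - aa, (n - row1) - (col1 - aa))
        if p <= obs:
            total += p
    return total


def all_tables(n_max: int):
    """Every 2x2 table of non-negative counts with 1 <= total <= n_max."""
    for n in range(1, n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c


def harrell_c_bruteforce(time, event, score) -> float:
    """Pair-enumeration Harrell's C (higher score predicts shorter survival)."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den
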