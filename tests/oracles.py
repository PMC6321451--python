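"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately uses a different algorithmic route than the code
it checks: pattern expansion + naive substring search for the IUPAC
matcher, exact-fraction hypergeometric enumeration for Fisher's test, and
explicit recursion over all nested structures for the folder.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "GA", "Y": "UC", "M": "AC", "K": "GU", "S": "GC", "W": "AU",
    "H": "ACU", "B": "GUC", "V": "GCA", "D": "GUA", "N": "GUAC",
}

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def expand_pattern(pattern: str) -> list[str]:
    """All concrete words an IUPAC pattern denotes."""
    return ["".join(w) for w in itertools.product(*(IUPAC[ch] for ch in pattern))]


def naive_matches(seq: str, pattern: str) -> list[tuple[int, int]]:
    """Brute-force matcher: expand to concrete words, naive substring scan."""
    w = len(pattern)
    starts: set[int] = set()
    for word in expand_pattern(pattern):
        i = seq.find(word)
        while i != -1:
            starts.add(i)
            i = seq.find(word, i + 1)
    return [(s, s + w) for s in sorted(starts)]


def hypergeom_tail_exact(p_with: int, p_total: int, n_with: int, n_total: int) -> Fraction:
    """Upper-tail hypergeometric probability as an exact fraction.

    Probability of >= p_with successes when drawing p_total from a
    population of p_total + n_total containing p_with + n_with successes.
    """
    M = p_total + n_total
    K = p_with + n_with
    N = p_total
    num = sum(comb(K, k) * comb(M - K, N - k) for k in range(p_with, min(K, N) + 1))
    return Fraction(num, comb(M, N))


def max_nested_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over all nested structures, by explicit recursion.

    Considers, for the first base of the interval, either leaving it
    unpaired or pairing it with every admissible partner; recursion over
    the two resulting sub-intervals enumerates every nested structure.
    """

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        m = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                m = max(m, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return m

    return best(0, len(seq) - 1)
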