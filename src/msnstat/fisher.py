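"""Fisher's exact test on two (mutant, total) read-count pairs.

The 2×2 contingency table compares mutant vs. wildtype read counts of two
samples::

            mutant   wildtype
    a       a_mut    a_tot - a_mut
    b       b_mut    b_tot - b_mut

P-values are computed by exact integer enumeration of the conditional
hypergeometric distribution: table probabilities share the common denominator
``C(N, mutant-column-sum)``, so "probability ≤ probability of the observed
table" is decided by comparing integer numerators — no floating-point tie
tolerance is involved, and a single float division happens at the end.  This
keeps results bit-reproducible and exactly matched to brute-force enumeration
(scipy's implementation is equivalent up to its 1e-7 relative tie guard and is
used as an independent cross-check in the test suite).
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

TWO_SIDED = "two-sided"
ONE_SIDED = "one-sided"
SIDEDNESS = (TWO_SIDED, ONE_SIDED)


def _check_pair(mutant: int, total: int, name: str) -> None:
    if mutant != int(mutant) or total != int(total):
        raise ValueError(f"{name}: read counts must be integers")
    if mutant < 0 or total < 0:
        raise ValueError(f"{name}: read counts must be non-negative")
    if mutant > total:
        raise ValueError(f"{name}: mutant reads ({mutant}) exceed total reads ({total})")


@lru_cache(maxsize=200_000)
def _fisher_table(a_mut: int, a_tot: int, b_mut: int, b_tot: int) -> tuple[float, float, float]:
    """(two_sided, lower_tail_for_a, upper_tail_for_a) for the observed table."""
    n = a_tot + b_tot
    m = a_mut + b_mut  # mutant-column margin
    lo = max(0, m - b_tot)
    hi = min(a_tot, m)
    # integer numerators over the common denominator C(n, m)
    nums = [comb(a_tot, k) * comb(b_tot, m - k) for k in range(lo, hi + 1)]
    denom = comb(n, m)
    obs = nums[a_mut - lo]
    two = sum(v for v in nums if v <= obs) / denom
    lower = sum(nums[: a_mut - lo + 1]) / denom
    upper = sum(nums[a_mut - lo:]) / denom
    return (min(two, 1.0), min(lower, 1.0), min(upper, 1.0))


def fisher_exact_p(a: tuple[int, int], b: tuple[int, int], sidedness: str = TWO_SIDED) -> float:
    """Exact p-value for equality of mutant-read frequency in two samples.

    Parameters
    ----------
    a, b
        ``(mutant, total)`` read counts of the two samples.
    sidedness
        ``"two-sided"`` (default): sum of probabilities of all tables with the
        observed margins that are no more probable than the observed table.
        ``"one-sided"``: the smaller tail of the observed table — the lower
        tail of the sample with the deficit of mutant reads (in the
        classifier's use, the zero-mutant non-positive sample).

    Returns
    -------
    float
        p-value in [0, 1].  ``1.0`` whenever either sample has ``total = 0``:
        a sample with no reads carries no evidence against the null.

    Notes
    -----
    Symmetric in its arguments for both sidedness modes: the lower tail of
    one sample's mutant count is the upper tail of the other's, so the
    smaller-tail rule does not depend on argument order.
    """
    a_mut, a_tot = a
    b_mut, b_tot = b
    _check_pair(a_mut, a_tot, "a")
    _check_pair(b_mut, b_tot, "b")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    if a_tot == 0 or b_tot == 0:
        return 1.0
    two, lower, upper = _fisher_table(int(a_mut), int(a_tot), int(b_mut), int(b_tot))
    if sidedness == TWO_SIDED:
        return two
    return min(lower, upper)
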