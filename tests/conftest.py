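"""Shared fixtures and independent test oracles."""

from fractions import Fraction
from math import comb

import pytest

from famvar.synthetic_cohort import FamilySimConfig, simulate_families


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by exhaustive enumeration of all
    2x2 tables with the observed margins: sum the hypergeometric
    probabilities of every table no more probable than the observed one.

    All probabilities share the denominator C(N, c1), so the comparison is
    done on integer numerators — no floating-point ties. Independent of the
    implementation under test.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)

    def numerator(x: int) -> int:
        return comb(r1, x) * comb(r2, c1 - x)

    n_obs = numerator(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(numerator(x) for x in range(lo, hi + 1) if numerator(x) <= n_obs)
    return Fraction(total, denom)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 12-family synthetic cohort with one planted causal variant
    and 500 designed-failure background variants."""
    return simulate_families(FamilySimConfig(seed=20240, n_background_variants=500))
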