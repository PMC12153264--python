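"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the exact
test oracle enumerates every 2x2 table with the observed margins using
exact rational arithmetic, and the nearest-pair oracle is a plain all-pairs
scan written straight from the gap definition.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from genecooc.synthetic import Fixture, fixture_from_counts


def fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by enumeration of all tables with the same margins.

    Probabilities are exact Fractions; a table contributes iff its
    probability is <= the observed table's (exact comparison). Returns the
    float value of the exact rational sum.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or 0 in (r1, n - r1, c1, n - c1):
        return 1.0
    denom = comb(n, c1)
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(k_min, k_max + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def two_sided_pvalues_for_margins(r1: int, c1: int, n: int) -> dict[int, float]:
    """Oracle two-sided p for every observed cell ``a`` attainable under
    margins (r1, n-r1; c1, n-c1), by exact-Fraction enumeration."""
    denom = comb(n, c1)
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(k_min, k_max + 1)
    }
    return {
        a: float(sum(p for p in probs.values() if p <= probs[a]))
        for a in probs
    }


def nearest_pair_bruteforce(anchor_genes, partner_genes):
    """All-pairs scan for the minimal same-contig gap; ties by starts.

    Returns ((distance, anchor_start, partner_start), anchor, partner) or
    None when no same-contig combination exists. Distance is recomputed
    inline from the ordered-boundary definition.
    """
    best = None
    for a in anchor_genes:
        for p in partner_genes:
            if a.contig_id != p.contig_id:
                continue
            left, right = (a, p) if (a.start, a.end) <= (p.start, p.end) else (p, a)
            gap = max(0, right.start - left.end - 1)
            key = (gap, a.start, p.start)
            if best is None or key < best[0]:
                best = (key, a, p)
    return best


@pytest.fixture(scope="session")
def printed_counts_fixture() -> Fixture:
    """The worked-example collection built from published table counts:
    501 + 72 archaeal and 164 + 14 bacterial anchor-positive genomes, the
    partner present only alongside the anchor, 163/501 archaeal and 127/164
    bacterial pairs below the 5 kb threshold, 9 + 1 tandem pairs."""
    return fixture_from_counts(
        501, 72, 164, 14,
        n_negative_arch=100, n_negative_bact=100,
        coloc_arch=163, coloc_bact=127,
        tandem_arch=9, tandem_bact=1,
    )
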