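"""Binomial likelihood of a high-homology reverse complement.

Quantifies how surprising it is to find a near-perfect (>= k-1 matching
bases) reverse complement of a k-bp motif within a given distance of its
locus, under a null of i.i.d. random sequence with a 25% per-base match
probability.

The enumeration follows the original three-term calculation: a 15-bp
comparison has 2^15 = 32,768 match/mismatch patterns, of which 31 reach
>= 14 matches - 15 single-mismatch patterns, 15 single-gap patterns and
the single perfect match.  The per-sequence probability

    P = p^k + k(1-p)p^(k-1) + k p^(k-1)

assigns each single-gap pattern probability p^(k-1) with no explicit
(1-p) factor for the gapped base; this idiosyncratic but published gap
term is the default (a conventional substitution-only binomial tail is
available via ``conventional=True``).  With 2(d+1) placement opportunities
within +/- d bp, the landscape-level p-value is their product, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom


@dataclass(frozen=True)
class EnrichmentParams:
    """k-bp motif, per-base match probability p, match floor, and observed separation d."""

    k: int = 15
    p: float = 0.25
    min_matches: int = 14
    distance: int = 1_366

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.min_matches > self.k:
            raise ValueError("min_matches cannot exceed k")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def pattern_count(k: int) -> int:
    """Number of match/mismatch patterns across a k-bp comparison: 2^k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2**k


def high_homology_pattern_count(k: int, min_matches: int) -> int:
    """Patterns with >= min_matches matches, counting single-gap patterns.

    Defined for the near-perfect case only: k + k + 1 patterns for
    min_matches = k-1 (k single mismatches, k single gaps, 1 perfect
    match), and 1 for a perfect match.
    """
    if min_matches > k:
        raise ValueError("min_matches cannot exceed k")
    if min_matches == k:
        return 1
    if min_matches == k - 1:
        return 2 * k + 1
    raise ValueError(
        "the enumeration is defined only for min_matches >= k-1 "
        f"(got min_matches={min_matches}, k={k})"
    )


def random_match_probability(
    params: EnrichmentParams = EnrichmentParams(), conventional: bool = False
) -> float:
    """Probability that a random k-bp sequence reaches >= k-1 matched bases.

    Default: the published three-term sum (perfect + single mismatch +
    single gap, the gap term weighted p^(k-1)).  ``conventional=True``
    instead returns the substitution-only binomial tail
    P(X >= min_matches), X ~ Binomial(k, p).
    """
    k, p = params.k, params.p
    if conventional:
        return float(binom.sf(params.min_matches - 1, k, p))
    return p**k + k * (1 - p) * p ** (k - 1) + k * p ** (k - 1)


def opportunity_count(distance: int) -> int:
    """Number of placements for the motif within +/- distance bp: 2(d+1)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return 2 * (distance + 1)


def landscape_pvalue(
    params: EnrichmentParams = EnrichmentParams(), conventional: bool = False
) -> float:
    """Likelihood of a >= (k-1)-match reverse complement within +/- d bp, capped at 1."""
    p = opportunity_count(params.distance) * random_match_probability(params, conventional)
    return min(1.0, p)


def enrichment_summary(
    params: EnrichmentParams = EnrichmentParams(), conventional: bool = False
) -> dict:
    """All five quantities of the enrichment calculation as a JSON-ready dict."""
    return {
        "pattern_count": pattern_count(params.k),
        "high_homology_pattern_count": high_homology_pattern_count(params.k, params.min_matches),
        "random_match_probability": random_match_probability(params, conventional),
        "opportunity_count": opportunity_count(params.distance),
        "landscape_pvalue": landscape_pvalue(params, conventional),
    }
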