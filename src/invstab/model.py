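"""Additive inverted-repeat instability scoring.

Each reverse-complement hit contributes a reactivity weight

    w = A * D^(-(m - m0) * (100/k) / 10) * f(d)

where ``m`` is the hit's effective mismatch count, ``m0`` a reference
mismatch count, ``D`` the homology decade factor (reactivity drops one
order of magnitude for every 10-percentage-point loss of homology, the
behaviour measured for inverted Alu recombination), and ``f`` a
non-increasing distance kernel on the hit's separation ``d`` from the
query, zero beyond the 421 kb reactive distance.  The instability of a
landscape is the sum of its hit weights, I = sum(w); the raw stability
score is S = 1 - I, exactly 1.0 for a landscape with no reactive hits.

The genome-wide inverted:direct Alu pair ratio that motivates this
weighting is 0.955 +/- 0.006 over 50-100 kb separations; it enters the
model only as the rationale for treating inverted homology as a
destabilising quantity, not as an arithmetic input.

Additivity is a deliberate modelling choice: it makes leave-one-out
contributions exact (I_total - I_excluded is precisely the excluded hit's
weight) and makes a duplicated hit contribute exactly twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .scanner import RevCompHit

ALU_ID_BASELINE = 0.955  # documented genome-wide inverted:direct Alu pair ratio

_KERNELS = ("uniform", "linear", "hyperbolic")


@dataclass(frozen=True)
class InstabilityParams:
    """Reactivity-weight parameters.

    A: weight of an m0-mismatch hit at distance 0 (default 5e-4, which puts
    a Table-1-like landscape's instability near 5.6e-4 with ~90% of it
    carried by a 2-mismatch hit at 1.4 kb).  homology_decade: reactivity
    drop factor per 10% homology loss (default 10 = one order of
    magnitude).  distance kernels: uniform f=1; linear f=max(0, 1-d/R);
    hyperbolic f=c/(c+d) with half-distance c in bp (default 10 kb).
    """

    A: float = 5e-4
    homology_decade: float = 10.0
    m0: int = 2
    kernel: str = "hyperbolic"
    c: float = 10_000.0
    reactive_distance: int = 421_000

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {_KERNELS}")
        if self.c <= 0:
            raise ValueError("kernel parameter c must be positive")


def _distance_factor(distance: int, params: InstabilityParams) -> float:
    if distance > params.reactive_distance:
        return 0.0
    if params.kernel == "uniform":
        return 1.0
    if params.kernel == "linear":
        return max(0.0, 1.0 - distance / params.reactive_distance)
    return params.c / (params.c + distance)


def _homology_factor(m: int, k: int, params: InstabilityParams) -> float:
    decades = (m - params.m0) * (100.0 / k) / 10.0
    return params.homology_decade ** (-decades)


def hit_weight(hit: RevCompHit, params: InstabilityParams = InstabilityParams()) -> float:
    """Reactivity weight of one hit; errors on hits beyond the reactive distance."""
    if hit.distance > params.reactive_distance:
        raise ValueError(
            f"hit at {hit.distance} bp exceeds reactive distance "
            f"{params.reactive_distance}; filter before weighting"
        )
    return (
        params.A
        * _homology_factor(hit.score.effective_mismatches, hit.score.k, params)
        * _distance_factor(hit.distance, params)
    )


@dataclass
class StabilityResult:
    """Raw stability S = 1 - sum(weights) with per-hit contributions (sorted descending)."""

    raw_stability: float
    contributions: List[Tuple[RevCompHit, float]] = field(default_factory=list)

    @property
    def instability(self) -> float:
        return 1.0 - self.raw_stability

    @property
    def raw_stability_reported(self) -> float:
        """S rounded to the 8 decimals used in printed stability tables."""
        return round(self.raw_stability, 8)


def raw_stability(
    hits: Sequence[RevCompHit], params: InstabilityParams = InstabilityParams()
) -> StabilityResult:
    """Additive stability of a hit list (hits beyond the reactive window are ignored)."""
    reactive = [h for h in hits if h.distance <= params.reactive_distance]
    contribs = [(h, hit_weight(h, params)) for h in reactive]
    contribs.sort(key=lambda hw: -hw[1])
    instability = sum(w for _, w in contribs)
    return StabilityResult(raw_stability=1.0 - instability, contributions=contribs)


def relative_stabilities(raw_scores: Sequence[float]) -> List[float]:
    """Per-haplotype stability relative to the most stable haplotype, in percent.

    With I_i = 1 - S_i and I_min the smallest instability in the set, the
    relative stability is 100 * (1 - (I_i - I_min)/I_min); the most stable
    haplotype scores exactly 100.00%.  Values are rounded to 2 decimals,
    the precision used in printed comparisons.
    """
    if len(raw_scores) < 2:
        raise ValueError("need >= 2 raw scores")
    if any(s > 1.0 for s in raw_scores):
        raise ValueError("raw stability scores cannot exceed 1.0")
    instabilities = [1.0 - s for s in raw_scores]
    i_min = min(instabilities)
    if i_min <= 0:
        raise ValueError("relative stability undefined when the most stable landscape has I = 0")
    return [round(100.0 * (1.0 - (i - i_min) / i_min), 2) for i in instabilities]


def stability_variation(relative_percents: Sequence[float]) -> float:
    """Spread of a relative-stability column: 100 - min, rounded to 1 decimal."""
    if len(relative_percents) < 2:
        raise ValueError("need >= 2 relative stabilities")
    return round(100.0 - min(relative_percents), 1)


def exclusion_analysis(
    hits: Sequence[RevCompHit],
    params: InstabilityParams = InstabilityParams(),
    exclude: Union[RevCompHit, str, None] = None,
) -> Tuple[StabilityResult, float]:
    """Leave-one-out stability: recompute without one hit and report its contribution.

    ``exclude`` may be a hit object or its locus string; by default the
    largest-weight hit is excluded.  The contribution fraction is
    (I_total - I_excluded) / I_total, which under the additive model is
    exactly the excluded hit's share of the instability.
    """
    total = raw_stability(hits, params)
    if not total.contributions:
        raise ValueError("no reactive hits to exclude")
    if exclude is None:
        target = total.contributions[0][0]
    elif isinstance(exclude, str):
        matches = [h for h in hits if h.locus == exclude]
        if not matches:
            raise KeyError(f"no hit with locus {exclude!r}")
        target = matches[0]
    else:
        if exclude not in list(hits):
            raise KeyError(f"hit {exclude.locus} not in the hit list")
        target = exclude
    remaining = [h for h in hits if h is not target]
    result = raw_stability(remaining, params)
    fraction = (total.instability - result.instability) / total.instability
    return result, fraction


def contribution_fraction(s_total: float, s_excluded: float) -> float:
    """Excluded-hit share of instability from two raw stability scores."""
    i_total = 1.0 - s_total
    if i_total <= 0:
        raise ValueError("total instability must be positive")
    return (i_total - (1.0 - s_excluded)) / i_total


# ---------------------------------------------------------------------------
# kernel calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelFit:
    params: InstabilityParams
    residuals: Tuple[float, ...]

    @property
    def A(self) -> float:
        return self.params.A

    @property
    def c(self) -> float:
        return self.params.c


def calibrate_kernel(
    hit_sets: Sequence[Sequence[RevCompHit]],
    target_scores: Sequence[float],
    params: InstabilityParams = InstabilityParams(),
) -> KernelFit:
    """Least-squares fit of the weight scale A (and, for the hyperbolic
    kernel, the half-distance c) to observed raw stability scores.

    Uniform and linear kernels are linear in A and solved in closed form;
    the hyperbolic kernel is fit with bounded nonlinear least squares.
    """
    if len(hit_sets) != len(target_scores):
        raise ValueError("hit_sets and target_scores must have equal length")
    n_unknowns = 2 if params.kernel == "hyperbolic" else 1
    if len(hit_sets) < n_unknowns:
        raise ValueError(
            f"{params.kernel} kernel has {n_unknowns} unknown(s) but only "
            f"{len(hit_sets)} observation(s)"
        )
    targets = np.asarray([1.0 - s for s in target_scores], dtype=float)

    def model_instability(A: float, c: float) -> np.ndarray:
        p = replace(params, A=A, c=c)
        return np.asarray([raw_stability(hs, p).instability for hs in hit_sets])

    if params.kernel in ("uniform", "linear"):
        basis = model_instability(1.0, params.c)
        denom = float(basis @ basis)
        if denom == 0:
            raise ValueError("degenerate calibration: all hit sets have zero basis weight")
        A_hat = float(basis @ targets) / denom
        if A_hat <= 0:
            raise ValueError("degenerate calibration: fitted A is not positive")
        fitted = replace(params, A=A_hat)
        res = tuple((1.0 - model_instability(A_hat, params.c)) - (1.0 - targets))
        return KernelFit(params=fitted, residuals=res)

    def fun(x: np.ndarray) -> np.ndarray:
        logA, logc = x
        return model_instability(math.exp(logA), math.exp(logc)) - targets

    x0 = np.array([math.log(params.A), math.log(params.c)])
    sol = least_squares(fun, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise ValueError(f"degenerate calibration: optimiser failed ({sol.message})")
    A_hat, c_hat = math.exp(sol.x[0]), math.exp(sol.x[1])
    fitted = replace(params, A=A_hat, c=c_hat)
    res = tuple(-fun(sol.x))
    return KernelFit(params=fitted, residuals=res)


def stability_report(
    per_haplotype: Dict[str, Sequence[RevCompHit]],
    params: InstabilityParams = InstabilityParams(),
    exclude_locus: Optional[str] = None,
) -> "pd.DataFrame":
    """Comparison table: mismatch-class counts, raw S, relative %, exclusion columns.

    The exclusion columns remove the shared top-weight hit (the locus with
    the largest weight in the most unstable haplotype unless given).
    """
    import pandas as pd

    from .scanner import classify_by_mismatch

    names = list(per_haplotype)
    results = {n: raw_stability(per_haplotype[n], params) for n in names}
    raw = [results[n].raw_stability for n in names]
    rel = relative_stabilities(raw)
    excl_scores = []
    for n in names:
        try:
            if exclude_locus is None:
                res, _ = exclusion_analysis(per_haplotype[n], params, None)
            else:
                res, _ = exclusion_analysis(per_haplotype[n], params, exclude_locus)
            excl_scores.append(res.raw_stability)
        except (KeyError, ValueError):
            excl_scores.append(results[n].raw_stability)
    rel_excl = relative_stabilities(excl_scores)
    rows = []
    for i, n in enumerate(names):
        counts = classify_by_mismatch(list(per_haplotype[n]))
        rows.append(
            {
                "haplotype": n,
                **{f"mm{m}": counts.get(m, 0) for m in (2, 3, 4, 5, 6)},
                "total": counts["total"],
                "raw_stability": round(raw[i], 8),
                "relative_pct": rel[i],
                "raw_stability_excl": round(excl_scores[i], 9),
                "relative_excl_pct": rel_excl[i],
            }
        )
    return pd.DataFrame(rows)
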