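"""Growth-rate feasibility of short fungal relative-abundance bursts.

A fungal ASV can jump from undetected to a quarter of all eukaryotic reads
within days.  Assuming the burst is in-situ growth (one organism multiplying
against an otherwise constant background, no losses), the specific growth
rate required to multiply a relative abundance by a factor ``x`` in ``t``
hours, starting from an initial cell fraction ``y``, is

    mu = (1/t) * log2( x - 1 + 1/(1 - x*y) )        ["printed" mode]

with ``mu`` in doublings per hour.  The exact inversion of the stated
two-population model (focal cells n0 * 2^(mu*t) against background (1 - y))
gives the slightly different

    mu = (1/t) * log2( x * (1 - y) / (1 - x*y) )    ["exact" mode]

The two agree as y -> 0 (both tend to log2(x)/t) and differ in the third
decimal for the worked detection-limit scenario; both are provided and the
difference is documented rather than resolved.  The detection limit of a
sample is one read over its total reads.  Verdicts compare ``mu`` with a
configurable range of published culture-based marine fungal growth rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_tables import DataError

#: Culture-based marine fungal growth-rate range (per hour) across organic
#: carbon substrates, used as the default feasibility benchmark.
DEFAULT_REFERENCE_RANGE = (0.01, 0.27)
#: Highest in-situ fungal growth rate reported (spring-bloom yeasts), h^-1.
IN_SITU_BENCHMARK = 0.045

MODES = ("printed", "exact")


@dataclass(frozen=True)
class GrowthScenario:
    """A feasibility calculation: multiply RA by ``x`` in ``t`` hours.

    ``y`` is the initial fraction of eukaryotic cells belonging to the
    organism; ``mu`` the required specific growth rate in doublings/hour.
    """

    x: float
    y: float
    t: float
    mu: float
    mode: str = "printed"


@dataclass(frozen=True)
class FeasibilityVerdict:
    mu: float
    reference_range: tuple
    verdict: str  # below | within | above


def detection_limit(total_reads: int) -> float:
    """Smallest detectable relative abundance: 1 read over the sample total."""
    if total_reads < 1:
        raise DataError("total_reads must be >= 1")
    return 1.0 / float(total_reads)


def implied_x(ra_final: float, y: float) -> float:
    """Fold change in relative abundance implied by a start fraction ``y``."""
    if y <= 0:
        raise DataError("undetectable start (y = 0): fold change x is unbounded")
    if not 0 < ra_final < 1:
        raise DataError("ra_final must lie in (0, 1)")
    return ra_final / y


def required_mu(x: float, y: float, t: float, mode: str = "printed") -> float:
    """Specific growth rate (doublings/hour) for an ``x``-fold RA increase.

    ``mode='printed'`` evaluates mu = (1/t) log2(x - 1 + 1/(1 - x y));
    ``mode='exact'`` the algebraic inversion mu = (1/t) log2(x (1-y)/(1 - x y)).
    Requires x > 0, y >= 0, x*y < 1 (the target abundance must be reachable)
    and t > 0.
    """
    if mode not in MODES:
        raise DataError(f"mode must be one of {MODES}")
    if x <= 0 or y < 0 or t <= 0:
        raise DataError("need x > 0, y >= 0, t > 0")
    if x * y >= 1:
        raise DataError("target abundance unreachable: x*y must be < 1")
    if mode == "printed":
        return math.log2(x - 1.0 + 1.0 / (1.0 - x * y)) / t
    return math.log2(x * (1.0 - y) / (1.0 - x * y)) / t


def scenario(x: float, y: float, t: float, mode: str = "printed") -> GrowthScenario:
    return GrowthScenario(x=x, y=y, t=t, mu=required_mu(x, y, t, mode=mode), mode=mode)


def feasibility(mu: float, reference_range: tuple = DEFAULT_REFERENCE_RANGE) -> FeasibilityVerdict:
    """Compare a required growth rate with a published range (inclusive)."""
    low, high = reference_range
    if low > high:
        raise DataError("reference range must satisfy low <= high")
    if mu < low:
        verdict = "below"
    elif mu > high:
        verdict = "above"
    else:
        verdict = "within"
    return FeasibilityVerdict(mu=mu, reference_range=(low, high), verdict=verdict)
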