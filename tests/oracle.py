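"""Independent oracles used by the test suite.

These are deliberately separate implementations — plain-Python scalar
loops and closed forms — against which the package's vectorized code is
checked.  They must stay independent of :mod:`meltdose` internals except
for the published model constants.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

# Published model constants (the contract under test, not shared code).
POOL_SCALE = 2.0
KAPPA = 36.0
TEMPLATE_LOAD = 5e-11


def brute_force_pcr(
    lengths: Sequence[float],
    primer_pools: Sequence[float],
    copies: Sequence[float],
    dntp_conc: float,
    cycles: int,
    efficiency: float,
) -> List[float]:
    """Scalar cycle-by-cycle recursion of the competitive-PCR model.

    Each cycle: per-amplicon demand = efficiency × completion × product,
    capped by its primer pool; if total nucleotide need exceeds the
    remaining shared dNTP pool, all demands scale by the same factor.
    Completion = min(1, κ·c₀/L) with c₀ the formulated concentration.
    """
    n = len(lengths)
    x = [copies[i] * TEMPLATE_LOAD for i in range(n)]
    primers = list(primer_pools)
    dntp = dntp_conc * POOL_SCALE
    comp = [min(1.0, KAPPA * dntp_conc / lengths[i]) for i in range(n)]
    for _ in range(cycles):
        demand = [
            min(efficiency * comp[i] * x[i], primers[i]) for i in range(n)
        ]
        need = sum(demand[i] * lengths[i] for i in range(n))
        if need > dntp and need > 0:
            f = dntp / need
            demand = [d * f for d in demand]
        for i in range(n):
            x[i] += demand[i]
            primers[i] -= demand[i]
        dntp -= sum(demand[i] * lengths[i] for i in range(n))
    return x


def logistic_melt_value(
    T: float, amounts: Sequence[float], lengths: Sequence[float],
    tms: Sequence[float], widths: Sequence[float],
) -> float:
    """Closed-form noiseless melt signal at one temperature."""
    total = 0.0
    for amt, L, tm, w in zip(amounts, lengths, tms, widths):
        total += amt * L / (1.0 + math.exp(-(tm - T) / w))
    return total


def neg_deriv_value(
    T: float, amounts: Sequence[float], lengths: Sequence[float],
    tms: Sequence[float], widths: Sequence[float],
) -> float:
    """Closed-form −dF/dT of the transition sum at one temperature."""
    total = 0.0
    for amt, L, tm, w in zip(amounts, lengths, tms, widths):
        s = 1.0 / (1.0 + math.exp(-(tm - T) / w))
        total += amt * L / w * s * (1.0 - s)
    return total


def analytic_peak_set(
    amounts: Sequence[float], lengths: Sequence[float],
    tms: Sequence[float], widths: Sequence[float],
    lo: float = 65.0, hi: float = 95.0, step: float = 0.002,
) -> List[Tuple[float, float]]:
    """Local maxima of the closed-form −dF/dT on a very fine scan."""
    peaks = []
    prev2 = neg_deriv_value(lo, amounts, lengths, tms, widths)
    prev1 = neg_deriv_value(lo + step, amounts, lengths, tms, widths)
    T = lo + 2 * step
    while T <= hi:
        cur = neg_deriv_value(T, amounts, lengths, tms, widths)
        if prev1 >= prev2 and prev1 > cur and prev1 > 1e-12:
            peaks.append((T - step, prev1))
        prev2, prev1 = prev1, cur
        T += step
    return peaks
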