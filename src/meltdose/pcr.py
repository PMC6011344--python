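"""Endpoint model of competitive multiplex PCR under a limited dNTP pool.

Co-amplified products share one dNTP pool and each has its own primer pool.
Run cycle by cycle, each amplicon tries to double at the per-cycle
efficiency; synthesis is capped jointly by the remaining shared dNTPs
(consumption proportional to new strands × length) and by its own remaining
primers (one primer pair per new strand).  When the pool cannot meet total
demand, the remainder is allocated proportionally to demand, so molar
product ratios — and hence initial template copy ratios — are preserved up
to the moment of exhaustion.  This is what makes endpoint melting-peak
heights quantitative: in the dNTP-limited regime amplification stops before
the primer-limitation plateau erases the copy-number signal.

Below the quantification window the polymerase can no longer complete long
templates within a cycle: extension capacity scales with the formulated
dNTP concentration, so the shortest amplicon gains a per-cycle advantage
that compounds into takeover, as observed when multiplex HRM assays are run
with too few nucleotides.

Units are dimensionless "reaction concentration" units: primer pools enter
in μM, the dNTP budget is μM × :data:`POOL_SCALE`, and templates load at
:data:`TEMPLATE_LOAD` units per genomic copy.  The mapping constants are
chosen so the classic concentration landmarks fall in the right regimes at
35 cycles: ≲1.56 μM shortest-amplicon takeover, ~6.25 μM limited
(quantitative), ≳25 μM primer plateau.
"""

from __future__ import annotations

from typing import Dict, Mapping

import numpy as np

from .models import GenotypeTruth, MeltdoseError, ReactionSpec

#: dNTP budget units per μM of formulated dNTP concentration.
POOL_SCALE = 2.0

#: Nucleotides of extension capacity per cycle per μM formulated dNTPs.
KAPPA = 36.0

#: Template product units contributed per genomic copy.
TEMPLATE_LOAD = 5e-11


def simulate_competitive_pcr(
    reaction: ReactionSpec,
    genotype: GenotypeTruth,
    template_load: float = TEMPLATE_LOAD,
    extra_copies: Mapping[str, float] | None = None,
    return_state: bool = False,
):
    """Run the cycle recursion and return endpoint product amounts.

    Parameters
    ----------
    reaction : ReactionSpec
        Amplicons, dNTP concentration (μM), cycle count and efficiency.
    genotype : GenotypeTruth
        Copy number per target locus; the reference locus is fixed at 2.
    template_load : float
        Product units of starting template per genomic copy.
    extra_copies : mapping, optional
        Fractional additional template copies per locus group, e.g. an
        *SMN2* mis-priming leak onto the *SMN1* locus.
    return_state : bool
        Also return the remaining dNTP budget and primer pools, for
        resource-balance checks.

    Returns
    -------
    dict
        Amplicon name → endpoint product amount (nonnegative).  A locus
        with zero copies yields exactly zero product.  With
        ``return_state``, a ``(products, state)`` tuple where ``state``
        holds ``dntp_remaining`` and ``primers_remaining``.
    """
    if reaction.dntp_conc <= 0:
        raise MeltdoseError("dntp_conc must be positive")
    for amp in reaction.targets:
        if amp.locus_group not in genotype.copies:
            raise MeltdoseError(
                f"genotype {genotype.label!r} lacks a copy number for "
                f"locus {amp.locus_group!r}"
            )

    amps = reaction.amplicons
    lengths = np.array([a.length for a in amps], dtype=float)
    primers = np.array([a.primer_conc for a in amps], dtype=float)
    extra = extra_copies or {}
    copies = np.array(
        [genotype.copy_number(a.locus_group) + extra.get(a.locus_group, 0.0)
         for a in amps],
        float,
    )

    x = copies * template_load
    dntp = reaction.dntp_conc * POOL_SCALE
    # Extension-completion factor: fraction of initiated strands the
    # polymerase finishes per cycle, set by the formulated concentration.
    completion = np.minimum(1.0, KAPPA * reaction.dntp_conc / lengths)

    for _ in range(reaction.cycles):
        demand = np.minimum(reaction.efficiency * completion * x, primers)
        need = float(np.dot(demand, lengths))
        if need > dntp:
            if need > 0:
                demand = demand * (dntp / need)
        x = x + demand
        primers = primers - demand
        dntp -= float(np.dot(demand, lengths))
        if dntp < 0.0:  # float dust after a fully-consumed pool
            dntp = 0.0

    products = {a.name: float(v) for a, v in zip(amps, x)}
    if return_state:
        state = {
            "dntp_remaining": dntp,
            "primers_remaining": {
                a.name: float(p) for a, p in zip(amps, primers)
            },
        }
        return products, state
    return products


def endpoint_ratios(
    products: Mapping[str, float], reaction: ReactionSpec
) -> Dict[str, float]:
    """Target/reference molar product ratios from an endpoint product map."""
    ref = products[reaction.reference.name]
    if ref <= 0:
        raise MeltdoseError("reference amplicon produced no product")
    return {a.name: products[a.name] / ref for a in reaction.targets}
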