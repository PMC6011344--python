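"""Forward model: from genotypes to raw high-resolution melting curves.

Each simulated sample runs its assay's reactions through the limited-dNTP
competitive PCR recursion (:mod:`meltdose.pcr`), then renders the endpoint
products as a fluorescence-versus-temperature curve:

    F(T) = gain · [ B·e^{−d·(T−T_min)} + Σᵢ amountᵢ·Lᵢ·σ((tmᵢ−T)/wᵢ) ] + ε

a decaying exponential dye background plus one symmetric two-state
(logistic) melting transition per amplicon, with signal proportional to
duplex base pairs (saturating-dye behaviour), and additive Gaussian noise.
Per-well nuisances emulate instrument reality: fluorescence gain,
background amplitude/decay, and a small well-to-well temperature offset
that shifts every Tm in the well coherently.

The noise scale ``noise_sd`` is a fraction of the reference transition's
analytic −dF/dT peak height (amount·L/(4w)), so "1% noise" means 1% of the
reference melting peak on the derivative plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import assays
from .models import (
    AmpliconSpec,
    CohortSpec,
    GenotypeTruth,
    MeltCurve,
    MeltdoseError,
    ReactionSpec,
)
from .pcr import simulate_competitive_pcr

GRID_START = 65.0
GRID_END = 95.0
GRID_STEP = 0.05


def default_grid(step: float = GRID_STEP) -> np.ndarray:
    """Uniform acquisition grid, 65–95 °C."""
    n = int(round((GRID_END - GRID_START) / step))
    return GRID_START + step * np.arange(n + 1)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def transition_sum(
    products: Mapping[str, float],
    amplicons: Sequence[AmpliconSpec],
    grid: np.ndarray,
    tm_shift: float = 0.0,
) -> np.ndarray:
    """Noiseless, background-free melt signal of a product mixture."""
    total = np.zeros_like(grid, dtype=float)
    for amp in amplicons:
        amount = products.get(amp.name, 0.0)
        if amount == 0.0:
            continue
        tm = amp.tm + tm_shift
        total += amount * amp.length * _logistic((tm - grid) / amp.melt_width)
    return total


def reference_peak_scale(
    products: Mapping[str, float], amplicons: Sequence[AmpliconSpec]
) -> float:
    """Analytic −dF/dT peak height of the reference transition (noise unit)."""
    for amp in amplicons:
        if amp.role == "reference":
            return products.get(amp.name, 0.0) * amp.length / (4.0 * amp.melt_width)
    heights = [
        products.get(a.name, 0.0) * a.length / (4.0 * a.melt_width)
        for a in amplicons
    ]
    return max(heights, default=0.0)


def synthesize_melt_curve(
    products: Mapping[str, float],
    amplicons: Sequence[AmpliconSpec],
    grid: np.ndarray,
    background: Tuple[float, float] = (0.0, 0.1),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    sample_id: str = "sample",
    tm_shift: float = 0.0,
    gain: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> MeltCurve:
    """Render endpoint products as a raw melt curve on ``grid``.

    ``background`` is ``(amplitude, decay_rate)`` of the exponential dye
    background referenced to the low-temperature end of the grid.  The
    grid must cover every amplicon's Tm with at least two melt widths of
    margin on both sides.
    """
    grid = np.asarray(grid, dtype=float)
    for amp in amplicons:
        if products.get(amp.name, 0.0) == 0.0:
            continue
        tm = amp.tm + tm_shift
        if tm - 2 * amp.melt_width < grid[0] or tm + 2 * amp.melt_width > grid[-1]:
            raise MeltdoseError(
                f"grid [{grid[0]}, {grid[-1]}] does not cover amplicon "
                f"{amp.name} (Tm {tm} ± 2×{amp.melt_width})"
            )

    amplitude, decay = background
    signal = transition_sum(products, amplicons, grid, tm_shift)
    bg = amplitude * np.exp(-decay * (grid - grid[0]))
    fluor = gain * (bg + signal)

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        scale = noise_sd * gain * reference_peak_scale(products, amplicons)
        fluor = fluor + rng.normal(0.0, scale, size=grid.shape)

    return MeltCurve(grid, fluor, sample_id, stage="raw")


@dataclass
class SimulatedSample:
    """One cohort member: truth plus one raw curve per reaction."""

    sample_id: str
    truth: GenotypeTruth
    curves: Dict[str, MeltCurve]


def generate_cohort(
    assay: str,
    spec: CohortSpec,
    grid: Optional[np.ndarray] = None,
    smn2_leak: float = 0.0,
) -> List[SimulatedSample]:
    """Simulate a seeded cohort for the ``sma`` or ``del22q`` assay.

    Controls listed in ``spec.controls`` occupy the first slots
    deterministically; the remaining samples draw genotype classes from
    ``spec.class_weights``.  Per-well gain, background and temperature
    jitter are drawn from one seeded stream, so identical seeds give
    bit-identical cohorts.

    ``smn2_leak`` adds that fraction of two *SMN2* copies to the *SMN1*
    template, modelling imperfect allele-specific priming (default: the
    allele-specific primer is fully specific).
    """
    if assay not in assays.ASSAYS:
        raise MeltdoseError(f"unknown assay {assay!r}")
    profile = assays.ASSAYS[assay]
    reactions: List[ReactionSpec] = profile["reactions"]
    genotypes: Mapping[str, GenotypeTruth] = profile["genotypes"]
    mandated = {gt.label for _, gt in profile["controls"]}
    provided = {gt.label for _, gt in spec.controls}
    missing = mandated - provided
    if missing:
        raise MeltdoseError(
            f"assay {assay!r} requires control classes {sorted(mandated)}; "
            f"missing {sorted(missing)}"
        )
    for label in spec.class_weights:
        if label not in genotypes:
            raise MeltdoseError(f"unknown genotype class {label!r} for {assay!r}")

    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(spec.seed)

    labels = [label for label, _ in spec.controls]
    truths = [gt for _, gt in spec.controls]
    n_random = spec.n_samples - len(spec.controls)
    class_labels = list(spec.class_weights)
    weights = np.array([spec.class_weights[c] for c in class_labels], float)
    drawn = rng.choice(len(class_labels), size=n_random, p=weights)
    for i, k in enumerate(drawn):
        labels.append(f"S{i + 1:04d}")
        truths.append(genotypes[class_labels[k]])

    samples: List[SimulatedSample] = []
    for sample_id, truth in zip(labels, truths):
        curves: Dict[str, MeltCurve] = {}
        for reaction in reactions:
            extra = (
                {"SMN1": 2.0 * smn2_leak}
                if smn2_leak > 0 and "SMN1" in truth.copies
                else None
            )
            products = simulate_competitive_pcr(reaction, truth, extra_copies=extra)
            plateau = sum(
                products[a.name] * a.length for a in reaction.amplicons
            )
            bg_amp = rng.uniform(0.3, 0.7) * max(plateau, 1e-12)
            bg_decay = rng.uniform(0.05, 0.15)
            tm_shift = rng.uniform(-0.3, 0.3)
            gain = rng.uniform(0.7, 1.3)
            curves[reaction.name] = synthesize_melt_curve(
                products,
                reaction.amplicons,
                grid,
                background=(bg_amp, bg_decay),
                noise_sd=spec.noise_sd,
                sample_id=sample_id,
                tm_shift=tm_shift,
                gain=gain,
                rng=rng,
            )
        samples.append(SimulatedSample(sample_id, truth, curves))
    return samples


def default_cohort_spec(
    assay: str,
    n_samples: int,
    seed: int,
    noise_sd: float = 0.01,
    class_weights: Optional[Mapping[str, float]] = None,
) -> CohortSpec:
    """Cohort spec with the assay's standard class mix and controls."""
    profile = assays.ASSAYS[assay]
    return CohortSpec(
        n_samples=n_samples,
        class_weights=dict(class_weights or profile["class_weights"]),
        noise_sd=noise_sd,
        seed=seed,
        controls=list(profile["controls"]),
    )
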