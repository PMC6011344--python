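"""Core domain types for melt-curve copy-number analysis.

The pipeline revolves around a handful of small value objects: the PCR
products being multiplexed (:class:`AmpliconSpec`, :class:`ReactionSpec`),
the simulated or known ground truth (:class:`GenotypeTruth`), the measured
signal (:class:`MeltCurve`, :class:`NegDerivCurve`), and the derived results
(:class:`Peak`, :class:`SampleCall`).  All temperatures are degrees Celsius;
fluorescence is in arbitrary instrument units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

ACQUISITION_RANGE = (65.0, 95.0)

REFERENCE = "reference"
TARGET = "target"

#: Processing stages a melt curve moves through.
STAGES = ("raw", "background_subtracted", "normalized", "shifted")


class MeltdoseError(ValueError):
    """Base class for input/contract violations raised by this package."""


@dataclass(frozen=True)
class AmpliconSpec:
    """One PCR product in a multiplex reaction.

    Parameters
    ----------
    name : str
        Label used in peak tables (typically the gene symbol).
    role : {"reference", "target"}
        Whether the amplicon is the two-copy internal reference or a
        dosage target.
    tm : float
        Expected melting temperature (°C) of the product.
    melt_width : float
        Logistic transition scale (°C) of the two-state melt.
    length : int
        Product length in base pairs; governs dNTP consumption and dye
        signal per molecule.
    primer_conc : float
        Concentration of each primer of the pair (μM); the per-amplicon
        primer pool.
    gene : str
        Gene symbol.
    locus_group : str
        Dosage locus the amplicon reports on ("REF" for the reference).
    """

    name: str
    role: str
    tm: float
    melt_width: float
    length: int
    primer_conc: float
    gene: str
    locus_group: str

    def __post_init__(self) -> None:
        if self.role not in (REFERENCE, TARGET):
            raise MeltdoseError(f"amplicon {self.name}: bad role {self.role!r}")
        lo, hi = ACQUISITION_RANGE
        if not lo <= self.tm <= hi:
            raise MeltdoseError(
                f"amplicon {self.name}: Tm {self.tm} outside acquisition "
                f"range [{lo}, {hi}]"
            )
        if self.melt_width <= 0:
            raise MeltdoseError(f"amplicon {self.name}: melt_width must be > 0")
        if self.length <= 0:
            raise MeltdoseError(f"amplicon {self.name}: length must be > 0")
        if self.primer_conc <= 0:
            raise MeltdoseError(f"amplicon {self.name}: primer_conc must be > 0")


@dataclass(frozen=True)
class ReactionSpec:
    """A duplex or triplex competitive PCR sharing one limited dNTP pool."""

    name: str
    amplicons: Tuple[AmpliconSpec, ...]
    dntp_conc: float = 6.25
    cycles: int = 35
    efficiency: float = 0.95

    def __post_init__(self) -> None:
        if not 2 <= len(self.amplicons) <= 3:
            raise MeltdoseError(
                f"reaction {self.name}: needs 2-3 amplicons, "
                f"got {len(self.amplicons)}"
            )
        if self.dntp_conc <= 0:
            raise MeltdoseError(f"reaction {self.name}: dntp_conc must be > 0")
        if not 0 <= self.efficiency <= 1:
            raise MeltdoseError(f"reaction {self.name}: efficiency outside [0, 1]")
        refs = [a for a in self.amplicons if a.role == REFERENCE]
        if len(refs) != 1:
            raise MeltdoseError(
                f"reaction {self.name}: exactly one reference amplicon "
                f"required, found {len(refs)}"
            )

    @property
    def reference(self) -> AmpliconSpec:
        return next(a for a in self.amplicons if a.role == REFERENCE)

    @property
    def targets(self) -> Tuple[AmpliconSpec, ...]:
        return tuple(a for a in self.amplicons if a.role == TARGET)

    def min_adjacent_tm_separation(self) -> float:
        """Smallest Tm gap between adjacent amplicons of this reaction."""
        tms = sorted(a.tm for a in self.amplicons)
        return min(b - a for a, b in zip(tms, tms[1:]))


@dataclass(frozen=True)
class GenotypeTruth:
    """Known integer copy numbers per dosage locus; reference fixed at 2."""

    copies: Mapping[str, int]
    label: str

    def __post_init__(self) -> None:
        for locus, n in self.copies.items():
            if not (isinstance(n, (int, np.integer)) and 0 <= n <= 3):
                raise MeltdoseError(
                    f"genotype {self.label}: copies[{locus}]={n!r} "
                    "must be an integer in 0..3"
                )

    def copy_number(self, locus_group: str) -> int:
        if locus_group == "REF":
            return 2
        return int(self.copies[locus_group])


@dataclass
class MeltCurve:
    """Fluorescence versus temperature on a uniform ascending grid."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    sample_id: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise MeltdoseError(
                f"curve {self.sample_id}: temperature/fluorescence length mismatch"
            )
        if self.temperatures.size < 3:
            raise MeltdoseError(f"curve {self.sample_id}: too few points")
        steps = np.diff(self.temperatures)
        if np.any(steps <= 0):
            raise MeltdoseError(f"curve {self.sample_id}: grid not ascending")
        if np.ptp(steps) > 0.01 * steps.mean():
            raise MeltdoseError(f"curve {self.sample_id}: grid not uniform")
        if self.stage not in STAGES:
            raise MeltdoseError(f"curve {self.sample_id}: unknown stage {self.stage!r}")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])

    def with_values(self, values: np.ndarray, stage: Optional[str] = None) -> "MeltCurve":
        return MeltCurve(
            self.temperatures.copy(),
            np.asarray(values, dtype=float),
            self.sample_id,
            stage or self.stage,
        )


@dataclass
class NegDerivCurve:
    """Negative first derivative −dF/dT of a processed melt curve."""

    temperatures: np.ndarray
    values: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.shape != self.values.shape:
            raise MeltdoseError(f"{self.sample_id}: grid/value length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise MeltdoseError(f"{self.sample_id}: non-finite derivative values")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class CursorPair:
    """Temperatures flanking the melt region, anchoring the background fit."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise MeltdoseError("cursors: left must be below right")


@dataclass(frozen=True)
class PeakWindow:
    """Expected location of one amplicon's melting peak."""

    amplicon: str
    center: float
    half_width: float = 1.5

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise MeltdoseError(f"window {self.amplicon}: half_width must be > 0")

    @property
    def low(self) -> float:
        return self.center - self.half_width

    @property
    def high(self) -> float:
        return self.center + self.half_width

    def overlaps(self, other: "PeakWindow") -> bool:
        return self.low < other.high and other.low < self.high


@dataclass
class Peak:
    """A melting-peak location and height on a −dF/dT curve."""

    temperature: float
    height: float
    amplicon: str
    sample_id: str
    absent: bool = False


@dataclass
class CohortSpec:
    """What a simulated cohort looks like: size, class mix, noise, controls."""

    n_samples: int
    class_weights: Mapping[str, float]
    noise_sd: float = 0.01
    seed: int = 0
    controls: Sequence[Tuple[str, GenotypeTruth]] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = float(sum(self.class_weights.values()))
        if abs(total - 1.0) > 1e-9:
            raise MeltdoseError(f"class_weights sum to {total}, expected 1")
        if self.n_samples < len(self.controls):
            raise MeltdoseError("n_samples smaller than the number of controls")
        if self.noise_sd < 0:
            raise MeltdoseError("noise_sd must be >= 0")


@dataclass
class SampleCall:
    """Final per-sample result: integer copies plus decoded phenotype."""

    sample_id: str
    copies: Dict[str, int]
    phenotype: str
    cluster_id: Dict[str, int] = field(default_factory=dict)
    dosage: Dict[str, float] = field(default_factory=dict)
    qc: str = "pass"


@dataclass
class ClusterResult:
    """Partition of a batch from agglomerative clustering in the sup metric."""

    labels: Dict[str, int]
    merge_heights: np.ndarray
    cut_height: float
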