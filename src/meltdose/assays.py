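"""Built-in assay definitions.

Two clinically motivated assays ship with the package:

``sma``
    A duplex reaction quantifying *SMN1* exon 7 dosage against a *CFTR*
    exon 7 reference.  Zero copies of *SMN1* cause spinal muscular
    atrophy; one copy marks a carrier.  An allele-specific primer keeps
    the near-identical *SMN2* out of the product pool.

``del22q``
    Two reactions per sample for 22q11.2 deletion syndrome: a duplex
    quantifying *CLTCL1* (between LCR22-A and LCR22-B) and a triplex
    quantifying *KLHL22* (LCR22-B..C) and *PI4KA* (LCR22-C..D), all
    against the same *CFTR* reference.  Which targets are hemizygous
    tells the deletion extent (A–B, A–C, A–D, or B–D).

Amplicon sizes, Tms and primer concentrations follow the published assay
design; the dNTP pool is the limited 6.25 μM that keeps endpoint product
ratios quantitative.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .models import AmpliconSpec, GenotypeTruth, PeakWindow, ReactionSpec

DEFAULT_MELT_WIDTH = 0.7  # °C logistic transition scale

CFTR = dict(name="CFTR", role="reference", tm=77.5, melt_width=DEFAULT_MELT_WIDTH,
            length=68, gene="CFTR", locus_group="REF")

AMPLICONS: Dict[str, AmpliconSpec] = {
    "SMN1": AmpliconSpec(name="SMN1", role="target", tm=73.5,
                         melt_width=DEFAULT_MELT_WIDTH, length=50,
                         primer_conc=0.5, gene="SMN1", locus_group="SMN1"),
    "CLTCL1": AmpliconSpec(name="CLTCL1", role="target", tm=85.0,
                           melt_width=DEFAULT_MELT_WIDTH, length=82,
                           primer_conc=0.5, gene="CLTCL1", locus_group="CLTCL1"),
    "KLHL22": AmpliconSpec(name="KLHL22", role="target", tm=90.0,
                           melt_width=DEFAULT_MELT_WIDTH, length=100,
                           primer_conc=1.0, gene="KLHL22", locus_group="KLHL22"),
    "PI4KA": AmpliconSpec(name="PI4KA", role="target", tm=83.0,
                          melt_width=DEFAULT_MELT_WIDTH, length=97,
                          primer_conc=0.5, gene="PI4KA", locus_group="PI4KA"),
}


def _cftr(primer_conc: float) -> AmpliconSpec:
    return AmpliconSpec(primer_conc=primer_conc, **CFTR)


SMA_DUPLEX = ReactionSpec(
    name="smn1_duplex",
    amplicons=(_cftr(0.25), AMPLICONS["SMN1"]),
)

DEL22Q_DUPLEX = ReactionSpec(
    name="cltcl1_duplex",
    amplicons=(_cftr(0.125), AMPLICONS["CLTCL1"]),
)

DEL22Q_TRIPLEX = ReactionSpec(
    name="klhl22_pi4ka_triplex",
    amplicons=(_cftr(0.125), AMPLICONS["KLHL22"], AMPLICONS["PI4KA"]),
)


def peak_windows(reaction: ReactionSpec, half_width: float = 1.5) -> List[PeakWindow]:
    return [PeakWindow(a.name, a.tm, half_width) for a in reaction.amplicons]


# ---------------------------------------------------------------------------
# Genotype catalogs

SMA_GENOTYPES: Dict[str, GenotypeTruth] = {
    "SMA": GenotypeTruth({"SMN1": 0}, "SMA"),
    "Carrier": GenotypeTruth({"SMN1": 1}, "Carrier"),
    "Normal": GenotypeTruth({"SMN1": 2}, "Normal"),
    "No SMA": GenotypeTruth({"SMN1": 3}, "No SMA"),
}

DEL22Q_GENOTYPES: Dict[str, GenotypeTruth] = {
    "Normal": GenotypeTruth(
        {"CLTCL1": 2, "KLHL22": 2, "PI4KA": 2}, "Normal"),
    "LCR22A-B": GenotypeTruth(
        {"CLTCL1": 1, "KLHL22": 2, "PI4KA": 2}, "LCR22A-B"),
    "LCR22A-C": GenotypeTruth(
        {"CLTCL1": 1, "KLHL22": 1, "PI4KA": 2}, "LCR22A-C"),
    "LCR22A-D": GenotypeTruth(
        {"CLTCL1": 1, "KLHL22": 1, "PI4KA": 1}, "LCR22A-D"),
    "LCR22B-D": GenotypeTruth(
        {"CLTCL1": 2, "KLHL22": 1, "PI4KA": 1}, "LCR22B-D"),
}

# Cohort class mixes mirroring the clinical validation cohorts: 103 samples
# referred for SMA testing (36 affected / 43 carriers / 23 normal / 1 with a
# duplication) and 99 samples screened for 22q11.2DS (43 deletion carriers,
# of whom ~87% span LCR22-A..D, ~8% A..B, and the remaining ~5% split
# between A..C and B..D).
SMA_CLASS_WEIGHTS: Dict[str, float] = {
    "SMA": 36 / 103,
    "Carrier": 43 / 103,
    "Normal": 23 / 103,
    "No SMA": 1 / 103,
}

_DEL_FRAC = 43 / 99
DEL22Q_CLASS_WEIGHTS: Dict[str, float] = {
    "Normal": 1 - _DEL_FRAC,
    "LCR22A-D": _DEL_FRAC * 0.87,
    "LCR22A-B": _DEL_FRAC * 0.08,
    "LCR22A-C": _DEL_FRAC * 0.025,
    "LCR22B-D": _DEL_FRAC * 0.025,
}

# Mandated controls run alongside every batch.
SMA_CONTROLS: List[Tuple[str, GenotypeTruth]] = [
    ("CTRL_2COPY", SMA_GENOTYPES["Normal"]),
    ("CTRL_1COPY", SMA_GENOTYPES["Carrier"]),
    ("CTRL_0COPY", SMA_GENOTYPES["SMA"]),
]

DEL22Q_CONTROLS: List[Tuple[str, GenotypeTruth]] = [
    ("CTRL_NORMAL", DEL22Q_GENOTYPES["Normal"]),
    ("CTRL_AD", DEL22Q_GENOTYPES["LCR22A-D"]),
]

ASSAYS: Dict[str, dict] = {
    "sma": dict(
        reactions=[SMA_DUPLEX],
        genotypes=SMA_GENOTYPES,
        class_weights=SMA_CLASS_WEIGHTS,
        controls=SMA_CONTROLS,
        baseline_control="CTRL_2COPY",
    ),
    "del22q": dict(
        reactions=[DEL22Q_DUPLEX, DEL22Q_TRIPLEX],
        genotypes=DEL22Q_GENOTYPES,
        class_weights=DEL22Q_CLASS_WEIGHTS,
        controls=DEL22Q_CONTROLS,
        baseline_control="CTRL_NORMAL",
    ),
}
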