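"""End-to-end analysis: raw melt CSV curves → per-sample copy-number calls.

One :func:`analyze_batch` call runs, per reaction: background subtraction,
helicity normalization, temperature shifting, Savitzky–Golay
differentiation, peak detection, batch peak normalization, relative
dosage, and per-target sup-metric clustering with control anchoring —
then assembles each sample's copy-number vector across reactions and
decodes the clinical class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import quantify as qt
from .calling import (
    CopyAssignment,
    assign_copy_numbers,
    decode_del22q,
    decode_sma,
    hierarchical_cluster,
)
from .config import AssayConfig
from .models import (
    MeltCurve,
    MeltdoseError,
    NegDerivCurve,
    Peak,
    PeakWindow,
    SampleCall,
)

log = logging.getLogger(__name__)


@dataclass
class ReactionAnalysis:
    """Intermediate per-reaction results, kept for reporting/plotting."""

    reaction: str
    curves: List[NegDerivCurve]
    peaks: List[List[Peak]]
    dosages: Dict[str, Dict[str, float]]      # sample -> target -> ratio
    assignments: Dict[str, Dict[str, CopyAssignment]]  # target -> sample -> asg
    excluded: List[str]          # failed reference peak
    preprocess_failed: List[str]  # unusable raw signal (e.g. no decay at cursor)
    shifts: np.ndarray


@dataclass
class BatchResult:
    calls: List[SampleCall]
    reactions: Dict[str, ReactionAnalysis] = field(default_factory=dict)

    def peaks_table(self) -> pd.DataFrame:
        rows = []
        for name, ra in self.reactions.items():
            for sample_peaks in ra.peaks:
                for p in sample_peaks:
                    rows.append(
                        {"sample_id": p.sample_id, "reaction": name,
                         "amplicon": p.amplicon,
                         "temperature": round(p.temperature, 4),
                         "height": round(p.height, 6),
                         "flag": "absent" if p.absent else "ok"}
                    )
        return pd.DataFrame(rows)

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            for locus, n in c.copies.items():
                rows.append(
                    {"sample_id": c.sample_id, "locus": locus, "copies": n,
                     "phenotype": c.phenotype,
                     "cluster_id": c.cluster_id.get(locus, -1),
                     "dosage_ratio": round(c.dosage.get(locus, float("nan")), 4),
                     "qc": c.qc}
                )
        return pd.DataFrame(rows)


def analyze_reaction(
    curves: Sequence[MeltCurve],
    config: AssayConfig,
    reaction_name: str,
) -> ReactionAnalysis:
    """Run the signal chain and per-target calling for one reaction."""
    reaction = config.reaction(reaction_name)
    windows = config.windows(reaction_name)
    ref_name = reaction.reference.name
    grid = curves[0].temperatures
    cursors = pp.default_cursors(
        reaction, grid,
        margin_widths=config.cursor_margin_widths,
        margin_extra=config.cursor_margin_extra,
        edge_clearance=config.slope_window / 2,
    )

    # Controls lead the batch so the shift reference is a control.
    order = sorted(
        range(len(curves)),
        key=lambda i: (curves[i].sample_id not in config.control_copies, i),
    )
    ordered = [curves[i] for i in order]

    normalized = []
    preprocess_failed: List[str] = []
    for c in ordered:
        try:
            normalized.append(
                pp.preprocess_curve(
                    c, cursors,
                    slope_window=config.slope_window, degree=config.sg_degree,
                )
            )
        except MeltdoseError as exc:
            if c.sample_id in config.control_copies:
                raise MeltdoseError(
                    f"control {c.sample_id!r} unusable in reaction "
                    f"{reaction_name!r}: {exc}"
                ) from exc
            log.warning(
                "excluding %s from %s: %s", c.sample_id, reaction_name, exc
            )
            preprocess_failed.append(c.sample_id)
    shift = pp.temperature_shift(
        normalized, band=config.shift_band, max_shift=config.max_shift
    )
    derivs = [
        pp.savitzky_golay_negderiv(c, window=config.sg_window, degree=config.sg_degree)
        for c in shift.curves
    ]
    peaks = [qt.detect_peaks(c, windows, reference=ref_name) for c in derivs]
    batch = qt.normalize_peaks_batch(
        derivs, peaks, ref_name, floor=config.reference_floor
    )

    baseline_id = config.baseline_control
    by_id = {c.sample_id: i for i, c in enumerate(batch.curves)}
    if baseline_id not in by_id:
        raise MeltdoseError(
            f"baseline control {baseline_id!r} missing from reaction "
            f"{reaction_name!r} batch"
        )
    target_names = [a.name for a in reaction.targets]
    baseline_peaks = batch.peaks[by_id[baseline_id]]
    dosages = {
        c.sample_id: qt.relative_dosage(ps, baseline_peaks, target_names)
        for c, ps in zip(batch.curves, batch.peaks)
    }

    assignments: Dict[str, Dict[str, CopyAssignment]] = {}
    for target in reaction.targets:
        window = next(w for w in windows if w.amplicon == target.name)
        controls = {
            sid: gt.copy_number(target.locus_group)
            for sid, gt in config.controls
            if sid in by_id
        }
        clusters = hierarchical_cluster(
            batch.curves, window, controls, linkage=config.linkage
        )
        target_dosage = {sid: d[target.name] for sid, d in dosages.items()}
        assignments[target.name] = assign_copy_numbers(
            clusters, controls, target_dosage,
            max_copies=config.max_copies,
            atypical_threshold=config.atypical_threshold,
        )

    return ReactionAnalysis(
        reaction=reaction_name,
        curves=batch.curves,
        peaks=batch.peaks,
        dosages=dosages,
        assignments=assignments,
        excluded=batch.excluded,
        preprocess_failed=preprocess_failed,
        shifts=shift.deltas,
    )


def analyze_batch(
    curves_by_reaction: Mapping[str, Sequence[MeltCurve]],
    config: AssayConfig,
) -> BatchResult:
    """Analyze all reactions of an assay and decode per-sample phenotypes."""
    expected = {r.name for r in config.reactions}
    got = set(curves_by_reaction)
    if expected != got:
        raise MeltdoseError(
            f"assay {config.name!r} expects reactions {sorted(expected)}, "
            f"got {sorted(got)}"
        )
    missing_controls = [
        sid for sid, _ in config.controls
        if any(
            sid not in {c.sample_id for c in curves}
            for curves in curves_by_reaction.values()
        )
    ]
    if missing_controls:
        raise MeltdoseError(
            f"mandated control samples missing from input: {missing_controls} "
            f"(assay {config.name!r} requires "
            f"{[sid for sid, _ in config.controls]})"
        )

    analyses = {
        name: analyze_reaction(curves, config, name)
        for name, curves in curves_by_reaction.items()
    }

    # Assemble per-sample copy vectors across reactions.
    locus_of = {}  # target amplicon -> locus_group
    for r in config.reactions:
        for t in r.targets:
            locus_of[t.name] = t.locus_group

    sample_ids: List[str] = []
    for curves in curves_by_reaction.values():
        for c in curves:
            if c.sample_id not in sample_ids:
                sample_ids.append(c.sample_id)

    failed_ref = set()
    dropped = set()
    for ra in analyses.values():
        failed_ref.update(ra.excluded)
        dropped.update(ra.preprocess_failed)

    calls: List[SampleCall] = []
    for sid in sample_ids:
        if sid in failed_ref or sid in dropped:
            qc = "failed_reference" if sid in failed_ref else "excluded"
            calls.append(SampleCall(sid, {}, "n/a", qc=qc))
            continue
        copies: Dict[str, int] = {}
        clusters: Dict[str, int] = {}
        dosage: Dict[str, float] = {}
        atypical = False
        for ra in analyses.values():
            for target, asg in ra.assignments.items():
                a = asg[sid]
                locus = locus_of[target]
                copies[locus] = a.copies
                clusters[locus] = a.cluster_id
                dosage[locus] = ra.dosages[sid][target]
                atypical = atypical or a.atypical
        phenotype = _decode(config.name, copies, atypical)
        calls.append(
            SampleCall(sid, copies, phenotype, clusters, dosage, qc="pass")
        )
    return BatchResult(calls, analyses)


def _decode(assay: str, copies: Mapping[str, int], atypical: bool) -> str:
    if assay == "sma":
        label = decode_sma(copies["SMN1"])
    elif assay == "del22q":
        label = decode_del22q(
            (copies["CLTCL1"], copies["KLHL22"], copies["PI4KA"])
        )
    else:
        raise MeltdoseError(f"no decoder for assay {assay!r}")
    if atypical:
        return "Atypical"
    return label
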