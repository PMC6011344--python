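"""Copy-number assignment: sup-metric clustering, control anchoring, decoding.

Normalized −dF/dT curves are compared in the uniform (sup/Chebyshev)
metric restricted to the target's peak window, so the partition is driven
by the target peak height — the dosage signal — rather than by noise
elsewhere on the curve.  Unbiased agglomerative clustering followed by a
largest-relative-gap cut groups samples of equal copy number; clusters
inherit integer copies from the controls they contain, and control-free
clusters (e.g. a rare duplication with no matching control) fall back to
rounding twice the median relative dosage of their members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .models import (
    ClusterResult,
    GenotypeTruth,
    MeltdoseError,
    NegDerivCurve,
    PeakWindow,
    SampleCall,
)

DEFAULT_LINKAGE = "average"
ATYPICAL_THRESHOLD = 0.35   # dosage distance from cluster expectation
MAX_COPIES = 4


def sup_distance(a: NegDerivCurve, b: NegDerivCurve, window: PeakWindow) -> float:
    """Uniform-metric distance restricted to a peak window."""
    if not np.array_equal(a.temperatures, b.temperatures):
        raise MeltdoseError("sup_distance requires a common grid")
    mask = (a.temperatures >= window.low) & (a.temperatures <= window.high)
    if not mask.any():
        raise MeltdoseError(f"window {window.amplicon} outside the common grid")
    return float(np.max(np.abs(a.values[mask] - b.values[mask])))


def hierarchical_cluster(
    curves: Sequence[NegDerivCurve],
    target_window: PeakWindow,
    controls: Mapping[str, int],
    linkage: str = DEFAULT_LINKAGE,
) -> ClusterResult:
    """Agglomerative clustering in the sup metric on the target window.

    The cut is the largest relative gap in merge heights, refined downward
    (more clusters) until controls of different copy number separate.
    Controls that cannot be separated at any cut mean the batch carries no
    usable dosage signal and the assay batch fails.
    """
    n = len(curves)
    if n < 2:
        raise MeltdoseError("clustering needs at least 2 samples")
    ids = [c.sample_id for c in curves]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = sup_distance(
                curves[i], curves[j], target_window
            )
    # Controls of different copy number sitting at ~zero distance mean
    # the batch carries no dosage signal at all; singleton cuts would
    # "separate" them vacuously, so reject up front.
    eps = 1e-9 * max(dist.max(), 1.0)
    ctrl_idx = [i for i, sid in enumerate(ids) if sid in controls]
    for ii, i in enumerate(ctrl_idx):
        for j in ctrl_idx[ii + 1:]:
            if controls[ids[i]] != controls[ids[j]] and dist[i, j] <= eps:
                raise MeltdoseError(
                    "assay batch failed: control samples of different copy "
                    f"number ({ids[i]}, {ids[j]}) are indistinguishable in "
                    "the target window"
                )

    z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    heights = z[:, 2]

    k0 = _gap_cut(heights)
    for k in range(k0, n + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if _controls_separated(ids, labels, controls):
            cut = float(heights[n - k]) if k < n else 0.0
            return ClusterResult(dict(zip(ids, labels.tolist())), heights, cut)
    raise MeltdoseError(
        "assay batch failed: control samples of different copy number "
        "cannot be separated at any cut"
    )


def _gap_cut(heights: np.ndarray) -> int:
    """Cluster count at the largest relative gap between merge heights."""
    n = heights.size + 1
    if heights.size < 2:
        return 2
    eps = 1e-12 * max(float(heights[-1]), 1.0) + 1e-300
    ratios = (heights[1:] + eps) / (heights[:-1] + eps)
    i = int(np.argmax(ratios))
    # cutting between merge i and i+1 leaves n-(i+1) clusters
    return n - (i + 1)


def _controls_separated(
    ids: List[str], labels: np.ndarray, controls: Mapping[str, int]
) -> bool:
    seen: Dict[int, int] = {}
    for sid, lab in zip(ids, labels):
        if sid in controls:
            copies = controls[sid]
            if lab in seen and seen[lab] != copies:
                return False
            seen[lab] = copies
    return True


@dataclass
class CopyAssignment:
    copies: int
    cluster_id: int
    atypical: bool


def assign_copy_numbers(
    clusters: ClusterResult,
    controls: Mapping[str, int],
    dosages: Mapping[str, float],
    max_copies: int = MAX_COPIES,
    atypical_threshold: float = ATYPICAL_THRESHOLD,
) -> Dict[str, CopyAssignment]:
    """Integer copies per sample from cluster membership.

    Clusters containing a control inherit its copy number; control-free
    clusters get round(2 × median member dosage), capped at
    ``max_copies``.  A member whose own dosage sits more than
    ``atypical_threshold`` from the cluster's expected ratio (copies/2)
    is flagged atypical.
    """
    missing = [sid for sid in controls if sid not in clusters.labels]
    if missing:
        raise MeltdoseError(f"controls absent from the batch: {missing}")
    members: Dict[int, List[str]] = {}
    for sid, lab in clusters.labels.items():
        members.setdefault(lab, []).append(sid)

    out: Dict[str, CopyAssignment] = {}
    for lab, sids in members.items():
        anchor = {controls[s] for s in sids if s in controls}
        if len(anchor) > 1:
            raise MeltdoseError(
                f"cluster {lab} contains controls of different copy number"
            )
        if anchor:
            copies = anchor.pop()
        else:
            med = float(np.median([dosages[s] for s in sids]))
            copies = int(min(math.floor(2.0 * med + 0.5), max_copies))
        expected = copies / 2.0
        for s in sids:
            atypical = abs(dosages[s] - expected) > atypical_threshold
            out[s] = CopyAssignment(copies, int(lab), atypical)
    return out


# ---------------------------------------------------------------------------
# Phenotype / deletion-class decoding

def decode_sma(copies: int) -> str:
    """SMN1 exon 7 dosage → clinical class (0 affected … ≥3 duplication)."""
    if copies < 0:
        raise MeltdoseError("copies must be nonnegative")
    if copies == 0:
        return "SMA"
    if copies == 1:
        return "Carrier"
    if copies == 2:
        return "Normal"
    return "No SMA"


_DEL22Q_CLASSES: Dict[Tuple[int, int, int], str] = {
    (2, 2, 2): "Normal",
    (1, 2, 2): "LCR22A-B",
    (1, 1, 2): "LCR22A-C",
    (1, 1, 1): "LCR22A-D",
    (2, 1, 1): "LCR22B-D",
}


def decode_del22q(copies: Tuple[int, int, int]) -> str:
    """(CLTCL1, KLHL22, PI4KA) copies → 22q11.2 deletion class.

    Hemizygosity patterns map onto which low-copy-repeat interval is
    deleted; any vector outside the recognized patterns is Atypical.
    """
    return _DEL22Q_CLASSES.get(tuple(int(c) for c in copies), "Atypical")


# ---------------------------------------------------------------------------
# Concordance against a truth table

@dataclass
class ConcordanceReport:
    overall: float
    n_samples: int
    per_class: pd.DataFrame
    mismatches: List[str]
    match: Dict[str, bool] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"samples compared: {self.n_samples}",
            f"overall concordance: {100 * self.overall:.1f}%",
        ]
        if self.mismatches:
            lines.append("mismatched samples: " + ", ".join(self.mismatches))
        else:
            lines.append("all individual sample copy numbers concordant")
        return "\n".join(lines)


def concordance_report(
    calls: Sequence[SampleCall],
    truth: Mapping[str, GenotypeTruth],
) -> ConcordanceReport:
    """Per-sample copy-number agreement between pipeline calls and truth.

    A sample counts as concordant only if every locus matches — aggregate
    class counts agreeing is not enough.
    """
    call_ids = {c.sample_id for c in calls}
    if call_ids != set(truth):
        raise MeltdoseError(
            "sample ids of calls and truth table differ: "
            f"only-in-calls={sorted(call_ids - set(truth))[:5]}, "
            f"only-in-truth={sorted(set(truth) - call_ids)[:5]}"
        )
    match: Dict[str, bool] = {}
    rows = []
    for call in calls:
        t = truth[call.sample_id]
        ok = all(
            call.copies.get(locus) == n for locus, n in t.copies.items()
        ) and len(call.copies) == len(t.copies)
        match[call.sample_id] = ok
        rows.append(
            {"sample_id": call.sample_id, "truth_label": t.label,
             "called": call.phenotype, "concordant": ok}
        )
    df = pd.DataFrame(rows)
    per_class = (
        df.groupby("truth_label")
        .agg(n=("concordant", "size"), n_concordant=("concordant", "sum"))
        .reset_index()
    )
    mismatches = sorted(df.loc[~df.concordant, "sample_id"])
    overall = float(df.concordant.mean())
    return ConcordanceReport(overall, len(df), per_class, mismatches, match)
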