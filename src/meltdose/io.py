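"""File formats: instrument-style wide melt CSV, TSV tables, run manifests.

Melt curves travel as wide CSV — a ``Temperature`` column followed by one
fluorescence column per sample — the shape most real-time PCR instruments
export.  The reader tolerates an optional unnamed leading index column
and resamples mildly non-uniform grids with a logged warning.  All other
tables (truth, peaks, calls, concordance) are plain TSV.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import ConcordanceReport
from .models import GenotypeTruth, MeltCurve, MeltdoseError

log = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def read_melt_csv(path: str | Path) -> List[MeltCurve]:
    """Read a wide melt CSV into one raw :class:`MeltCurve` per column."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    named = [h for h in header if h]
    dupes = {h for h in named if named.count(h) > 1}
    if dupes:
        raise MeltdoseError(f"{path}: duplicate sample ids {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns.size and str(df.columns[0]).startswith("Unnamed"):
        log.info("%s: dropping unnamed leading index column", path.name)
        df = df.iloc[:, 1:]
    if df.columns.size < 2:
        raise MeltdoseError(f"{path}: need a Temperature column plus samples")
    if df.columns[0] != "Temperature":
        raise MeltdoseError(
            f"{path}: first column must be 'Temperature', got {df.columns[0]!r}"
        )
    samples = list(df.columns[1:])
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.nonzero((bad | df[col].isna()).to_numpy())[0][0])
            raise MeltdoseError(
                f"{path}: non-numeric or missing value at row {row + 2}, "
                f"column {col!r}"
            )
    temps = df["Temperature"].to_numpy(dtype=float)
    steps = np.diff(temps)
    if np.any(steps <= 0):
        raise MeltdoseError(f"{path}: temperature grid must be ascending")
    uniform = np.ptp(steps) <= 0.01 * steps.mean()
    if not uniform:
        log.warning(
            "%s: non-uniform temperature grid (step %.4g–%.4g); resampling",
            path.name, steps.min(), steps.max(),
        )
        step = float(np.median(steps))
        new_temps = temps[0] + step * np.arange(
            int(np.floor((temps[-1] - temps[0]) / step)) + 1
        )
    else:
        new_temps = temps
    curves = []
    for s in samples:
        values = df[s].to_numpy(dtype=float)
        if not uniform:
            values = np.interp(new_temps, temps, values)
        curves.append(MeltCurve(new_temps.copy(), values, str(s), stage="raw"))
    return curves


def write_melt_csv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    """Write curves sharing one grid as wide CSV (writer inverse of reader)."""
    if not curves:
        raise MeltdoseError("no curves to write")
    grid = curves[0].temperatures
    for c in curves:
        if not np.array_equal(c.temperatures, grid):
            raise MeltdoseError("write_melt_csv requires a common grid")
    columns = {"Temperature": grid}
    columns.update({c.sample_id: c.fluorescence for c in curves})
    pd.DataFrame(columns).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_truth_tsv(
    truths: Mapping[str, GenotypeTruth], path: str | Path
) -> None:
    rows = [
        {"sample_id": sid, "locus": locus, "copies": n, "label": gt.label}
        for sid, gt in truths.items()
        for locus, n in gt.copies.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> Dict[str, GenotypeTruth]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "locus", "copies", "label"}
    if not required.issubset(df.columns):
        raise MeltdoseError(f"{path}: truth table needs columns {sorted(required)}")
    out: Dict[str, GenotypeTruth] = {}
    for sid, group in df.groupby("sample_id", sort=False):
        copies = {row.locus: int(row.copies) for row in group.itertuples()}
        out[str(sid)] = GenotypeTruth(copies, str(group.label.iloc[0]))
    return out


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "locus", "copies", "phenotype", "qc"}
    if not required.issubset(df.columns):
        raise MeltdoseError(f"{path}: calls table needs columns {sorted(required)}")
    return df


def write_concordance(
    report: ConcordanceReport, path_tsv: str | Path, path_txt: str | Path
) -> None:
    report.per_class.to_csv(path_tsv, sep="\t", index=False)
    Path(path_txt).write_text(report.summary() + "\n")


def write_manifest(
    path: str | Path,
    seed: int | None,
    config_hash: str,
    parameters: Mapping,
) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "software": "meltdose",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "parameters": dict(parameters),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
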