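"""Assay configuration: schema, YAML loading, validation, builtin profiles.

An :class:`AssayConfig` bundles everything `analyze` needs: the reactions
(amplicons with expected Tms), peak windows, control samples with known
copy numbers, and the preprocessing/calling parameters.  The builtin
``sma`` and ``del22q`` profiles reproduce the published assay designs
verbatim; a YAML file can override any of it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .models import (
    AmpliconSpec,
    GenotypeTruth,
    MeltdoseError,
    PeakWindow,
    ReactionSpec,
)

SCHEMA_VERSION = 1

# Multiplexed amplicons should melt 2–10 °C apart: closer and the peaks
# blur together, farther and one product dominates dye partitioning.
TM_SEPARATION_RULE = (2.0, 10.0)


@dataclass
class AssayConfig:
    name: str
    reactions: List[ReactionSpec]
    controls: List[Tuple[str, GenotypeTruth]]
    baseline_control: str
    window_half_width: float = 1.5
    sg_window: float = 1.0
    sg_degree: int = 2
    slope_window: float = 2.0
    shift_band: Tuple[float, float] = (5.0, 10.0)
    max_shift: float = 1.0
    cursor_margin_widths: float = 5.0
    cursor_margin_extra: float = 1.5
    linkage: str = "average"
    atypical_threshold: float = 0.35
    max_copies: int = 4
    reference_floor: float = 0.1

    @property
    def control_copies(self) -> Dict[str, GenotypeTruth]:
        return dict(self.controls)

    def reaction(self, name: str) -> ReactionSpec:
        for r in self.reactions:
            if r.name == name:
                return r
        raise MeltdoseError(f"assay {self.name!r} has no reaction {name!r}")

    def windows(self, reaction_name: str) -> List[PeakWindow]:
        r = self.reaction(reaction_name)
        return [PeakWindow(a.name, a.tm, self.window_half_width) for a in r.amplicons]

    def config_hash(self) -> str:
        blob = json.dumps(_serializable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def builtin_config(assay: str) -> AssayConfig:
    """The shipped ``sma`` or ``del22q`` profile."""
    from . import assays

    if assay not in assays.ASSAYS:
        raise MeltdoseError(
            f"unknown assay {assay!r}; builtin profiles: {sorted(assays.ASSAYS)}"
        )
    profile = assays.ASSAYS[assay]
    return AssayConfig(
        name=assay,
        reactions=list(profile["reactions"]),
        controls=list(profile["controls"]),
        baseline_control=profile["baseline_control"],
    )


def validate_config(cfg: AssayConfig) -> List[str]:
    """Design-rule violations: hard errors raise, soft rules return warnings.

    Overlapping peak windows and missing controls are errors.  The Tm
    separation rule (2–10 °C between co-amplified products) produces
    warnings only — a pairwise gap above 10 °C can be unavoidable in a
    triplex whose adjacent gaps are all compliant.
    """
    warnings: List[str] = []
    for r in cfg.reactions:
        windows = cfg.windows(r.name)
        for i, w in enumerate(windows):
            for other in windows[i + 1:]:
                if w.overlaps(other):
                    raise MeltdoseError(
                        f"reaction {r.name}: peak windows of {w.amplicon} "
                        f"and {other.amplicon} overlap"
                    )
        tms = sorted((a.tm, a.name) for a in r.amplicons)
        for (t1, n1), (t2, n2) in zip(tms, tms[1:]):
            gap = t2 - t1
            if gap < TM_SEPARATION_RULE[0]:
                warnings.append(
                    f"reaction {r.name}: adjacent ΔTm {n1}/{n2} = {gap:.1f} °C "
                    f"below the {TM_SEPARATION_RULE[0]} °C design rule"
                )
        for i, (t1, n1) in enumerate(tms):
            for t2, n2 in tms[i + 1:]:
                if t2 - t1 > TM_SEPARATION_RULE[1]:
                    warnings.append(
                        f"reaction {r.name}: pairwise ΔTm {n1}/{n2} = "
                        f"{t2 - t1:.1f} °C exceeds the "
                        f"{TM_SEPARATION_RULE[1]} °C design rule"
                    )
    if not cfg.controls:
        raise MeltdoseError(f"assay {cfg.name}: no control samples configured")
    if cfg.baseline_control not in {sid for sid, _ in cfg.controls}:
        raise MeltdoseError(
            f"assay {cfg.name}: baseline control {cfg.baseline_control!r} "
            "is not among the configured controls"
        )
    return warnings


def load_config(path: str | Path) -> AssayConfig:
    """Load an assay config from YAML (or a builtin profile by name).

    A file containing only ``assay: sma`` (or ``del22q``) loads the
    builtin profile; any other keys override profile fields.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise MeltdoseError(f"{path}: config must be a mapping")
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise MeltdoseError(f"{path}: unsupported schema_version {version}")
    assay = data.pop("assay", None)
    if assay is not None and "reactions" not in data:
        cfg = builtin_config(assay)
        cfg = _apply_overrides(cfg, data)
    else:
        cfg = _parse_full(data, assay)
    validate_config(cfg)
    return cfg


def save_config(cfg: AssayConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"schema_version": SCHEMA_VERSION, **_serializable(cfg)},
            fh,
            sort_keys=False,
        )


_SCALAR_FIELDS = (
    "window_half_width", "sg_window", "sg_degree", "slope_window",
    "max_shift", "cursor_margin_widths", "cursor_margin_extra", "linkage",
    "atypical_threshold", "max_copies", "reference_floor", "baseline_control",
)


def _apply_overrides(cfg: AssayConfig, data: Mapping) -> AssayConfig:
    for key, value in data.items():
        if key == "shift_band":
            cfg.shift_band = (float(value[0]), float(value[1]))
        elif key in _SCALAR_FIELDS:
            setattr(cfg, key, value)
        else:
            raise MeltdoseError(f"unknown config key {key!r}")
    return cfg


def _parse_full(data: Mapping, assay: Optional[str]) -> AssayConfig:
    try:
        reactions = [
            ReactionSpec(
                name=r["name"],
                amplicons=tuple(AmpliconSpec(**a) for a in r["amplicons"]),
                dntp_conc=float(r.get("dntp_conc", 6.25)),
                cycles=int(r.get("cycles", 35)),
                efficiency=float(r.get("efficiency", 0.95)),
            )
            for r in data["reactions"]
        ]
        controls = [
            (c["sample_id"], GenotypeTruth(dict(c["copies"]), c.get("label", "")))
            for c in data["controls"]
        ]
    except KeyError as exc:
        raise MeltdoseError(f"config missing required key: {exc}") from exc
    cfg = AssayConfig(
        name=assay or data.get("name", "custom"),
        reactions=reactions,
        controls=controls,
        baseline_control=data.get(
            "baseline_control", controls[0][0] if controls else ""
        ),
    )
    extras = {
        k: v for k, v in data.items()
        if k not in ("name", "reactions", "controls", "baseline_control")
    }
    return _apply_overrides(cfg, extras)


def _serializable(cfg: AssayConfig) -> dict:
    return {
        "name": cfg.name,
        "reactions": [
            {
                "name": r.name,
                "dntp_conc": r.dntp_conc,
                "cycles": r.cycles,
                "efficiency": r.efficiency,
                "amplicons": [asdict(a) for a in r.amplicons],
            }
            for r in cfg.reactions
        ],
        "controls": [
            {"sample_id": sid, "copies": dict(gt.copies), "label": gt.label}
            for sid, gt in cfg.controls
        ],
        "baseline_control": cfg.baseline_control,
        **{k: getattr(cfg, k) for k in _SCALAR_FIELDS if k != "baseline_control"},
        "shift_band": list(cfg.shift_band),
    }
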