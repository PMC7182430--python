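"""Feature-table I/O, run configuration, and report writing.

The interchange format is CSV: feature tables carry ``feature_id, mz,
rt_min`` followed by replicate intensity columns whose roles are inferred
from the ``sample_``/``control_`` prefixes.  The pipeline starts after peak
picking, so no raw-spectrum formats are involved.  Run configuration is a
flat ``key: value`` text file covering the filter thresholds, annotation
tolerance, simulation conditions and geometry constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import Annotation, annotations_frame
from .filtering import Feature, FilterAudit, FilterConfig, MolecularEvent
from .geometry import GeometryParams
from .simulate import SimConfig, features_to_frame, frame_to_features

__all__ = [
    "Experiment",
    "RunConfig",
    "read_feature_table",
    "write_report",
    "events_frame",
]


@dataclass
class Experiment:
    """A loaded feature table with channel roles and metadata."""

    features: list[Feature]
    sample_labels: list[str]
    control_labels: list[str]
    protein_input_uM: float = 1.0  # injection normalization per input protein
    marker_protein: str = ""
    domain: str = ""  # MCC or MCP

    def __post_init__(self) -> None:
        if not self.sample_labels or not self.control_labels:
            raise ValueError("need at least one sample and one control channel")


def read_feature_table(path: str | Path, **metadata) -> Experiment:
    """Read a feature-table CSV into an :class:`Experiment`.

    Columns ``feature_id, mz, rt_min`` are mandatory; intensity columns are
    recognized by their ``sample_``/``control_`` prefixes.  Duplicate feature
    ids and non-numeric cells are rejected.
    """
    frame = pd.read_csv(path)
    for col in ("feature_id", "mz", "rt_min"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    sample_cols = [c for c in frame.columns if c.startswith("sample_")]
    control_cols = [c for c in frame.columns if c.startswith("control_")]
    if not sample_cols or not control_cols:
        raise ValueError(f"{path}: need sample_* and control_* intensity columns")
    dup = frame["feature_id"][frame["feature_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature ids: {sorted(set(map(str, dup)))}")
    numeric = ["mz", "rt_min"] + sample_cols + control_cols
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            bad = frame.loc[coerced.isna(), "feature_id"].tolist()
            raise ValueError(f"{path}: non-numeric {col!r} for features {bad}")
        frame[col] = coerced
    return Experiment(
        features=frame_to_features(frame),
        sample_labels=sample_cols,
        control_labels=control_cols,
        **metadata,
    )


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    mz_tol_ppm: float = 5.0
    rt_window: float = 0.5
    seed: int = 0
    outdir: str = "results"

    _SECTIONS = ("filter", "sim", "geometry")

    def to_text(self) -> str:
        lines = []
        for section in self._SECTIONS:
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                value = getattr(obj, f.name)
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                lines.append(f"{section}.{f.name}: {value}")
        for name in ("mz_tol_ppm", "rt_window", "seed", "outdir"):
            lines.append(f"{name}: {getattr(self, name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        sections: dict[str, dict] = {s: {} for s in cls._SECTIONS}
        top: dict[str, str] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"config line {lineno}: expected 'key: value'")
            key, value = (part.strip() for part in line.split(":", 1))
            if "." in key:
                section, name = key.split(".", 1)
                if section not in sections:
                    raise ValueError(f"config line {lineno}: unknown section {section!r}")
                sections[section][name] = value
            else:
                top[key] = value
        kwargs: dict = {}
        section_types = {"filter": FilterConfig, "sim": SimConfig, "geometry": GeometryParams}
        for section, typ in section_types.items():
            fields = {f.name: f for f in dataclasses.fields(typ)}
            values = {}
            for name, raw_value in sections[section].items():
                if name not in fields:
                    raise ValueError(f"unknown config key {section}.{name}")
                values[name] = _coerce(raw_value, getattr(typ(), name))
            kwargs[section] = typ(**values)
        defaults = cls()
        for name in ("mz_tol_ppm", "rt_window", "seed", "outdir"):
            if name in top:
                kwargs[name] = _coerce(top.pop(name), getattr(defaults, name))
        if top:
            raise ValueError(f"unknown config keys: {sorted(top)}")
        return cls(**kwargs)


def _coerce(raw: str, template):
    if isinstance(template, tuple):
        parts = [p for p in raw.split(",") if p != ""]
        elem = template[0] if template else 0.0
        return tuple(type(elem)(p) for p in parts)
    if isinstance(template, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(raw)
    if isinstance(template, float):
        return float(raw)
    return raw


def events_frame(events: Sequence[MolecularEvent]) -> pd.DataFrame:
    """Molecular events → CSV-shaped table with member lists."""
    return pd.DataFrame(
        [
            {
                "event_id": e.representative.feature_id,
                "mz": e.mz,
                "rt_min": e.rt,
                "mean_sample_intensity": e.mean_sample,
                "n_members": len(e.members),
                "member_ids": ";".join(e.member_ids),
            }
            for e in events
        ],
        columns=[
            "event_id",
            "mz",
            "rt_min",
            "mean_sample_intensity",
            "n_members",
            "member_ids",
        ],
    )


def write_report(
    outdir: str | Path,
    features: Sequence[Feature] | None = None,
    events: Sequence[MolecularEvent] | None = None,
    audit: FilterAudit | None = None,
    annotations: Sequence[Annotation] | None = None,
    quant: pd.DataFrame | None = None,
    ratios: dict | None = None,
    geometry: dict | None = None,
) -> list[str]:
    """Write the deterministic result file set; returns the manifest.

    Only sections that were provided are written: ``features.csv``,
    ``events.csv``, ``audit.json``, ``annotations.csv``, ``quant.csv``,
    ``ratios.json``, ``geometry.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(str(path))

    if features is not None:
        emit("features.csv", lambda p: features_to_frame(features).to_csv(p, index=False))
    if events is not None:
        emit("events.csv", lambda p: events_frame(events).to_csv(p, index=False))
    if audit is not None:
        emit("audit.json", lambda p: Path(p).write_text(audit.to_json() + "\n"))
    if annotations is not None:
        emit(
            "annotations.csv",
            lambda p: annotations_frame(annotations).to_csv(p, index=False),
        )
    if quant is not None:
        emit("quant.csv", lambda p: quant.to_csv(p, index=False))
    if ratios is not None:
        emit(
            "ratios.json",
            lambda p: Path(p).write_text(json.dumps(ratios, indent=2, sort_keys=True) + "\n"),
        )
    if geometry is not None:
        emit(
            "geometry.json",
            lambda p: Path(p).write_text(json.dumps(geometry, indent=2, sort_keys=True) + "\n"),
        )
    return manifest
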