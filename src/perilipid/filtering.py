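"""Ion-filtering cascade for SMALP feature tables.

Detected ions are reduced to unique molecular events in four stages:

1. **Enrichment** against polymer-only control channels (mean sample
   intensity at least ``enrichment_fold`` times the mean control intensity,
   with a pseudo-count guarding against empty controls).
2. **Censoring** of solvent ions and inorganic salt clusters, recognized by
   anomalously low mass defects or by arithmetic ladders spaced by a salt
   cluster unit (sodium formate by default).
3. **Isotope collapse**: an M+1 feature merges into its parent when it sits
   one 13C–12C spacing higher, co-elutes, and is not brighter than the
   plausible first-isotope fraction.
4. **Adduct/dimer collapse**: co-eluting alternate adducts of one molecule
   merge (the deprotonated form is the canonical representative) and [2M-H]-
   dimers of a detected parent are removed.

Every stage reports kept + removed = input, and the whole cascade is
insensitive to the input ordering of features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import C13_C12_DELTA, FORMIC_ACID_MASS, PROTON_MASS, SODIUM_FORMATE_MASS

__all__ = [
    "Feature",
    "FilterConfig",
    "MolecularEvent",
    "FilterAudit",
    "enrichment_filter",
    "mass_defect_censor",
    "collapse_isotopes",
    "collapse_adducts_dimers",
    "filter_pipeline",
]


@dataclass(frozen=True)
class Feature:
    """One detected ion: m/z, retention time, and replicate intensities."""

    feature_id: str
    mz: float
    rt: float
    sample_intensities: tuple[float, ...]
    control_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: mz must be positive")
        if not self.sample_intensities or not self.control_intensities:
            raise ValueError(f"{self.feature_id}: empty intensity vector")

    @property
    def mean_sample(self) -> float:
        return float(np.mean(self.sample_intensities))

    @property
    def mean_control(self) -> float:
        return float(np.mean(self.control_intensities))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    ``enrichment_fold`` is inclusive (≥), matching the "at least 10-fold"
    decision rule.  ``pseudo_count`` (one intensity unit) stabilizes the
    ratio when controls are blank.  ``defect_slope`` sets the lower bound
    ``fractional(mz) ≥ defect_slope × mz`` below which an ion is treated as
    an inorganic cluster; organic lipids in the 250–1600 m/z window sit well
    above it.
    """

    enrichment_fold: float = 10.0
    pseudo_count: float = 1.0
    mz_tol_ppm: float = 5.0
    rt_tol_min: float = 0.1
    isotope_ratio_max: float = 0.6
    defect_slope: float = 0.00045
    salt_unit_masses: tuple[float, ...] = (SODIUM_FORMATE_MASS,)
    min_ladder_len: int = 3
    censor_mz_range: tuple[float, float] = (250.0, 1600.0)
    # above ~1.2 kDa the cumulative defect of CH2-rich lipids wraps past a
    # full Dalton (cardiolipins), so the fractional lower bound is only
    # applied below this mass; the ladder detector covers the rest
    defect_rule_mz_max: float = 1200.0
    adduct_deltas: tuple[float, ...] = (FORMIC_ACID_MASS,)

    def mz_tol(self, mz: float) -> float:
        return self.mz_tol_ppm * 1e-6 * mz


@dataclass
class MolecularEvent:
    """A unique molecule: a representative feature plus collapsed redundancy."""

    representative: Feature
    members: list[Feature] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def mz(self) -> float:
        return self.representative.mz

    @property
    def rt(self) -> float:
        return self.representative.rt

    @property
    def mean_sample(self) -> float:
        return self.representative.mean_sample

    @property
    def member_ids(self) -> list[str]:
        return [m.feature_id for m in self.members]

    @property
    def all_features(self) -> list[Feature]:
        return [self.representative] + self.members

    @property
    def all_ids(self) -> list[str]:
        return [f.feature_id for f in self.all_features]


@dataclass
class FilterAudit:
    """Feature counts surviving each stage of the cascade."""

    input: int = 0
    enriched: int = 0
    after_censor: int = 0
    after_dedup: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "enriched": self.enriched,
            "after_censor": self.after_censor,
            "after_dedup": self.after_dedup,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def _canonical_order(features: Sequence[Feature]) -> list[Feature]:
    # descending intensity, ties by lower m/z then id: makes the greedy
    # merging independent of input order
    return sorted(features, key=lambda f: (-f.mean_sample, f.mz, f.feature_id))


def enrichment_filter(
    features: Sequence[Feature], cfg: FilterConfig | None = None
) -> tuple[list[Feature], list[Feature], dict[str, float]]:
    """Keep features whose mean sample intensity is ≥ fold × mean control.

    Returns (kept, removed, ratios) where ratios maps feature_id to the
    pseudo-counted enrichment ratio.
    """
    cfg = cfg or FilterConfig()
    kept, removed, ratios = [], [], {}
    for f in features:
        ratio = f.mean_sample / (f.mean_control + cfg.pseudo_count)
        ratios[f.feature_id] = ratio
        (kept if ratio >= cfg.enrichment_fold else removed).append(f)
    return kept, removed, ratios


def _find_salt_ladders(
    features: Sequence[Feature], cfg: FilterConfig
) -> set[str]:
    """Feature ids belonging to arithmetic ladders spaced by a salt unit.

    Features are joined whenever their m/z difference is an exact multiple of
    the cluster unit (within tolerance); a connected component spanning at
    least ``min_ladder_len`` distinct rungs is a cluster ladder.  Counting
    distinct rungs keeps co-incident ions from two overlapping ladders from
    hiding each other.
    """
    ladder_ids: set[str] = set()
    order = sorted(features, key=lambda f: f.mz)
    n = len(order)
    for unit in cfg.salt_unit_masses:
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        max_span = cfg.min_ladder_len * 3 * unit  # limit pairwise scan window
        for i, a in enumerate(order):
            for j in range(i + 1, n):
                delta = order[j].mz - a.mz
                if delta > max_span:
                    break
                k = round(delta / unit)
                if k >= 1 and abs(delta - k * unit) <= cfg.mz_tol(order[j].mz):
                    parent[find(i)] = find(j)
        components: dict[int, list[int]] = {}
        for i in range(n):
            components.setdefault(find(i), []).append(i)
        for members in components.values():
            if len(members) < cfg.min_ladder_len:
                continue
            base = order[members[0]].mz
            rungs = {round((order[i].mz - base) / unit) for i in members}
            if len(rungs) >= cfg.min_ladder_len:
                ladder_ids.update(order[i].feature_id for i in members)
    return ladder_ids


def mass_defect_censor(
    features: Sequence[Feature], cfg: FilterConfig | None = None
) -> tuple[list[Feature], list[Feature], dict[str, str]]:
    """Censor inorganic salt clusters and cluster ladders.

    Within the analyzed m/z window, an ion is censored when its fractional
    mass falls below ``defect_slope × mz`` (CH2-rich organics accumulate
    ~0.0008 Da of defect per Da; inorganic clusters do not), or when it is a
    rung of a ladder of ≥ ``min_ladder_len`` features spaced by a salt unit.
    Features outside the window pass through untouched.
    """
    cfg = cfg or FilterConfig()
    lo, hi = cfg.censor_mz_range
    in_range = [f for f in features if lo <= f.mz <= hi]
    ladder_ids = _find_salt_ladders(in_range, cfg)
    kept, censored, reasons = [], [], {}
    for f in features:
        if not (lo <= f.mz <= hi):
            kept.append(f)
            continue
        defect = f.mz - np.floor(f.mz)
        if f.mz <= cfg.defect_rule_mz_max and defect < cfg.defect_slope * f.mz:
            censored.append(f)
            reasons[f.feature_id] = "low_mass_defect"
        elif f.feature_id in ladder_ids:
            censored.append(f)
            reasons[f.feature_id] = "salt_ladder"
        else:
            kept.append(f)
    return kept, censored, reasons


def collapse_isotopes(
    features: Sequence[Feature], cfg: FilterConfig | None = None
) -> list[MolecularEvent]:
    """Merge M+1 (and chained M+2…) isotope features into their parents.

    Greedy by descending mean sample intensity; a candidate B joins event A
    when B sits one 13C spacing above any current member of A, co-elutes
    within ``rt_tol_min``, and has intensity ≤ ``isotope_ratio_max`` of the
    member it stacks on.
    """
    cfg = cfg or FilterConfig()
    order = _canonical_order(features)
    events: list[MolecularEvent] = []
    assigned: set[str] = set()
    for f in order:
        if f.feature_id in assigned:
            continue
        event = MolecularEvent(representative=f)
        assigned.add(f.feature_id)
        members = [f]
        grew = True
        while grew:
            grew = False
            for cand in order:
                if cand.feature_id in assigned:
                    continue
                for m in members:
                    if (
                        abs(cand.mz - m.mz - C13_C12_DELTA) <= cfg.mz_tol(cand.mz)
                        and abs(cand.rt - m.rt) <= cfg.rt_tol_min
                        and m.mean_sample > 0
                        and cand.mean_sample / m.mean_sample <= cfg.isotope_ratio_max
                    ):
                        event.members.append(cand)
                        event.provenance[cand.feature_id] = "isotope"
                        assigned.add(cand.feature_id)
                        members.append(cand)
                        grew = True
                        break
        events.append(event)
    return events


def collapse_adducts_dimers(
    events: Sequence[MolecularEvent], cfg: FilterConfig | None = None
) -> list[MolecularEvent]:
    """Merge co-eluting alternate adducts and remove [2M-H]- dimers.

    Two events at the same retention time whose m/z differ by a registered
    neutral adduct delta (formic acid by default, linking [M-H]- and
    [M+HCOO]-) are one molecule; the lower-m/z (deprotonated) form becomes
    the representative.  An event sitting at 2 × m/z + one proton of any
    member form of a surviving event, at the same retention time, is that
    molecule's [2M-H]- dimer and is absorbed.
    """
    cfg = cfg or FilterConfig()
    pool = sorted(events, key=lambda e: (-e.mean_sample, e.mz, e.representative.feature_id))
    absorbed: set[str] = set()

    def absorb(into: MolecularEvent, other: MolecularEvent, tag: str) -> None:
        for f in other.all_features:
            into.members.append(f)
            into.provenance[f.feature_id] = tag
        into.provenance.update(other.provenance)
        absorbed.add(other.representative.feature_id)

    # adduct pairs first
    for i, a in enumerate(pool):
        if a.representative.feature_id in absorbed:
            continue
        for b in pool[i + 1 :]:
            if b.representative.feature_id in absorbed:
                continue
            if abs(a.rt - b.rt) > cfg.rt_tol_min:
                continue
            delta = abs(a.mz - b.mz)
            if any(abs(delta - d) <= cfg.mz_tol(max(a.mz, b.mz)) for d in cfg.adduct_deltas):
                # the lower-m/z (deprotonated) form is the canonical event
                low, high = (a, b) if a.mz < b.mz else (b, a)
                absorb(low, high, "alternate_adduct")
                if high is a:
                    break
    survivors = [e for e in pool if e.representative.feature_id not in absorbed]
    # dimers: check 2m + H for every member form of every surviving molecule
    final_absorbed: set[str] = set()
    for parent in survivors:
        if parent.representative.feature_id in final_absorbed:
            continue
        targets = [2.0 * f.mz + PROTON_MASS for f in parent.all_features]
        for cand in survivors:
            if cand is parent or cand.representative.feature_id in final_absorbed:
                continue
            if abs(cand.rt - parent.rt) > cfg.rt_tol_min:
                continue
            if any(abs(cand.mz - t) <= cfg.mz_tol(cand.mz) for t in targets):
                for f in cand.all_features:
                    parent.members.append(f)
                    parent.provenance[f.feature_id] = "dimer"
                parent.provenance.update(cand.provenance)
                final_absorbed.add(cand.representative.feature_id)
    return [e for e in survivors if e.representative.feature_id not in final_absorbed]


def filter_pipeline(
    features: Sequence[Feature], cfg: FilterConfig | None = None
) -> tuple[list[MolecularEvent], FilterAudit]:
    """Run the full cascade: enrichment → censor → isotope → adduct/dimer."""
    cfg = cfg or FilterConfig()
    audit = FilterAudit(input=len(features))
    enriched, _, _ = enrichment_filter(features, cfg)
    audit.enriched = len(enriched)
    kept, _, _ = mass_defect_censor(enriched, cfg)
    audit.after_censor = len(kept)
    events = collapse_isotopes(kept, cfg)
    events = collapse_adducts_dimers(events, cfg)
    audit.after_dedup = len(events)
    return events, audit
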