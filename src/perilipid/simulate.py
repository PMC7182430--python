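"""Synthetic HPLC-ESI-QToF experiments with known ground truth.

Every downstream stage of the pipeline is validated against data produced
here: feature tables that emulate a reversed-phase negative/positive-mode
lipidomics run of SMALP samples against polymer-only controls, standard
series for the calibration code, and membrane-positioned toy structures for
the geometry code.

The generator plants, for each true lipid species drawn from the theoretical
library: the monoisotopic ion at its library m/z, an M+1 isotope one
13C–12C spacing higher (first-order binomial intensity fraction
0.0108 × nC), a co-eluting alternate adduct, and — for the brightest decile
— a [2M-H]- dimer.  Contaminants comprise sodium-formate salt-cluster
ladders (enriched, so they reach the censoring stage) and solvent ions of
comparable intensity in sample and control channels (removed by the
enrichment filter).  Retention times follow a linear reversed-phase model in
chain length and unsaturation; replicate intensities carry multiplicative
log-normal noise.

Everything is a deterministic function of (seed, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    FORMIC_ACID_MASS,
    C13_C12_DELTA,
    PROTON_MASS,
    SODIUM_FORMATE_MASS,
    LibraryConfig,
    LipidClass,
    LipidSpecies,
    build_library,
    default_adduct,
    ionize,
)
from .filtering import Feature
from .geometry import MembraneStructure
from .quant import (
    ERGOSTEROL_SPIKE_GRID,
    PHOSPHOLIPID_SPIKE_GRID,
    StandardSeries,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_COMPOSITION",
    "generate_ground_truth",
    "render_features",
    "add_contaminants",
    "simulate_experiment",
    "simulate_standard_series",
    "evaluate_filter_run",
    "features_to_frame",
    "frame_to_features",
    "write_feature_table",
    "write_truth",
    "synthetic_ring_structure",
    "synthetic_transporter_conformers",
    "write_membrane_pdb",
]

#: default class composition (mol%), patterned on the yeast plasma membrane:
#: PC ~40, PI ~20, PE ~18, PS ~16, ergosterol ~4, with minor PA/PG/CL and the
#: two sphingolipids at trace level
DEFAULT_COMPOSITION: dict[LipidClass, float] = {
    LipidClass.PC: 38.0,
    LipidClass.PI: 19.0,
    LipidClass.PE: 17.0,
    LipidClass.PS: 15.0,
    LipidClass.ERG: 4.0,
    LipidClass.PA: 1.0,
    LipidClass.PG: 1.0,
    LipidClass.CL: 1.0,
    LipidClass.IPC: 2.0,
    LipidClass.MIPC: 2.0,
}

#: reversed-phase retention offsets per class (minutes)
RT_CLASS_OFFSET: dict[LipidClass, float] = {
    LipidClass.PC: 2.0,
    LipidClass.PE: 2.5,
    LipidClass.PS: 1.5,
    LipidClass.PI: 1.0,
    LipidClass.PG: 1.8,
    LipidClass.PA: 2.2,
    LipidClass.CL: 4.0,
    LipidClass.DAG: 5.0,
    LipidClass.IPC: 3.0,
    LipidClass.MIPC: 2.4,
    LipidClass.ERG: 6.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the emulated experiment.

    Three biological replicates against three polymer-only control channels,
    a 20-minute gradient, 10% replicate CV, and true lipid ions enriched at
    least 50-fold over the control before noise.
    """

    n_replicates: int = 3
    control_channels: int = 3
    gradient_span_min: float = 20.0
    noise_cv: float = 0.10
    enrichment_factor: float = 50.0
    enrichment_spread: float = 100.0  # enrichment drawn log-uniform in [f, f*spread]
    rt_carbon_coef: float = 0.25  # min per acyl carbon
    rt_db_coef: float = 0.60  # min lost per double bond
    response_per_pmol: float = 1.0e4  # peak intensity per pmol
    total_pmol: float = 100.0
    adduct_fraction: float = 0.30
    dimer_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.control_channels < 1:
            raise ValueError("need at least one sample and one control channel")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.gradient_span_min <= 0:
            raise ValueError("gradient span must be positive")


@dataclass
class GroundTruth:
    """Planted species and the registry of every rendered feature."""

    species: list[tuple[LipidSpecies, float]]  # (species, pmol)
    seed: int
    registry: dict[str, dict] = field(default_factory=dict)

    def ids_with_role(self, *roles: str) -> set[str]:
        return {fid for fid, rec in self.registry.items() if rec["role"] in roles}


def generate_ground_truth(
    seed: int,
    n_species: int = 50,
    composition: Mapping[LipidClass, float] | None = None,
    library_config: LibraryConfig | None = None,
) -> GroundTruth:
    """Draw a set of true lipid species with per-species pmol amounts.

    Species are sampled from the theoretical library in proportion to the
    class composition; each class's total amount (``total_pmol`` × mol%) is
    split among its species by a symmetric Dirichlet.  Deterministic for a
    fixed seed.
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    total_pct = sum(composition.values())
    if not (80.0 <= total_pct <= 120.0):
        raise ValueError("composition must sum to ~100%")
    rng = np.random.default_rng(seed)
    library = build_library(library_config)
    # one library row per species under its class-default adduct
    lib = library[
        library.apply(lambda r: r["adduct"] == default_adduct(LipidClass(r["class"])).name, axis=1)
    ]

    def chain_weights(pool: pd.DataFrame, cls: LipidClass) -> np.ndarray:
        # realistic acyl-chain distribution: diacyl species cluster around
        # 32 carbons / 1 double bond, cardiolipin around 68, ceramide
        # backbones around 44
        if cls is LipidClass.CL:
            c0, c_sd = 68.0, 4.0
        elif cls in (LipidClass.IPC, LipidClass.MIPC):
            c0, c_sd = 44.0, 1.5
        else:
            c0, c_sd = 32.0, 3.0
        w = np.exp(-0.5 * ((pool["carbons"].to_numpy() - c0) / c_sd) ** 2)
        w *= np.exp(-0.5 * ((pool["double_bonds"].to_numpy() - 1.0) / 1.5) ** 2)
        return w / w.sum()
    classes = sorted(composition, key=lambda c: LipidClass(c).value)
    weights = np.array([composition[c] for c in classes], dtype=float)
    weights /= weights.sum()
    # allocate species counts per class (ERG contributes exactly one species)
    counts = {c: 0 for c in classes}
    draws = rng.choice(len(classes), size=n_species, p=weights)
    for i in draws:
        counts[classes[i]] += 1
    species: list[tuple[LipidSpecies, float]] = []
    for cls in classes:
        cls = LipidClass(cls)
        n_cls = counts[cls]
        if n_cls == 0:
            continue
        pool = lib[lib["class"] == cls.value]
        if cls is LipidClass.ERG:
            n_cls = 1
        if n_cls > len(pool):
            raise ValueError(f"{cls.value}: {n_cls} species requested, library has {len(pool)}")
        rows = pool.iloc[
            sorted(
                rng.choice(
                    len(pool), size=n_cls, replace=False, p=chain_weights(pool, cls)
                )
            )
        ]
        class_pmol = SimConfig().total_pmol * composition[cls] / total_pct
        shares = rng.dirichlet(np.full(n_cls, 2.0)) if n_cls > 1 else np.array([1.0])
        for (_, row), share in zip(rows.iterrows(), shares):
            sp = LipidSpecies(LipidClass(row["class"]), int(row["carbons"]), int(row["double_bonds"]))
            species.append((sp, float(class_pmol * share)))
    species.sort(key=lambda t: (t[0].lipid_class.value, t[0].carbons, t[0].double_bonds))
    return GroundTruth(species=species, seed=seed)


def _retention_time(sp: LipidSpecies, cfg: SimConfig) -> float:
    raw = (
        RT_CLASS_OFFSET[sp.lipid_class]
        + cfg.rt_carbon_coef * sp.carbons
        - cfg.rt_db_coef * sp.double_bonds
    )
    if sp.lipid_class is LipidClass.ERG:
        raw = RT_CLASS_OFFSET[LipidClass.ERG] + cfg.rt_carbon_coef * 28
    return float(np.clip(raw, 0.5, cfg.gradient_span_min - 0.5))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _alternate_adduct_shift(cls: LipidClass) -> float | None:
    """m/z offset from the class-primary ion to its alternate adduct form."""
    primary = default_adduct(cls).name
    if primary == "[M-H]-":
        return +FORMIC_ACID_MASS  # [M+HCOO]- runs one neutral formic acid higher
    if primary == "[M+HCOO]-":
        return -FORMIC_ACID_MASS
    return None  # ergosterol: positive mode only, no alternate form


def render_features(truth: GroundTruth, cfg: SimConfig | None = None) -> list[Feature]:
    """Render the feature table for a ground truth: parents plus artifacts.

    Populates ``truth.registry`` with one record per rendered feature:
    role ``species`` / ``isotope`` / ``adduct`` / ``dimer`` with parent links.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng((truth.seed, 0x5EED))
    truth.registry.clear()
    features: list[Feature] = []
    counter = 0

    def emit(mz: float, rt: float, sample: np.ndarray, control: np.ndarray,
             role: str, parent: str | None, species: str | None) -> str:
        nonlocal counter
        counter += 1
        fid = f"F{counter:05d}"
        features.append(
            Feature(
                feature_id=fid,
                mz=round(mz, 6),
                rt=round(rt, 4),
                sample_intensities=tuple(np.round(sample, 2)),
                control_intensities=tuple(np.round(control, 2)),
            )
        )
        truth.registry[fid] = {"role": role, "parent": parent, "species": species}
        return fid

    base_intensities = np.array([pmol * cfg.response_per_pmol for _, pmol in truth.species])
    decile_cut = (
        np.quantile(base_intensities, 0.9) if len(base_intensities) else np.inf
    )

    for (sp, pmol), base in zip(truth.species, base_intensities):
        adduct = default_adduct(sp.lipid_class)
        mz = ionize(sp.monoisotopic_mass, adduct)
        rt = _retention_time(sp, cfg)
        enrichment = cfg.enrichment_factor * math.exp(
            rng.uniform(0.0, math.log(cfg.enrichment_spread))
        )
        control_base = base / enrichment

        def channels(level: float) -> tuple[np.ndarray, np.ndarray]:
            s = level * _lognormal_factors(rng, cfg.noise_cv, cfg.n_replicates)
            c = (level * control_base / base) * _lognormal_factors(
                rng, cfg.noise_cv, cfg.control_channels
            )
            return s, c

        s, c = channels(base)
        pid = emit(mz, rt, s, c, "species", None, sp.name)

        # M+1 isotope: first-order 13C binomial fraction
        n_carbon = sp.formula["C"]
        iso_frac = 0.0108 * n_carbon
        s, c = channels(base * iso_frac)
        emit(mz + C13_C12_DELTA, rt + rng.uniform(-0.01, 0.01), s, c, "isotope", pid, sp.name)

        shift = _alternate_adduct_shift(sp.lipid_class)
        if shift is not None:
            s, c = channels(base * cfg.adduct_fraction)
            emit(mz + shift, rt + rng.uniform(-0.01, 0.01), s, c, "adduct", pid, sp.name)

        if base >= decile_cut and adduct.charge_sign < 0:
            s, c = channels(base * cfg.dimer_fraction)
            emit(2.0 * mz + PROTON_MASS, rt + rng.uniform(-0.01, 0.01), s, c, "dimer", pid, sp.name)

    return features


def add_contaminants(
    features: list[Feature],
    seed: int,
    n_salt_ladders: int = 4,
    n_solvent: int = 12,
    cfg: SimConfig | None = None,
    registry: dict[str, dict] | None = None,
) -> list[Feature]:
    """Append salt-cluster ladders and solvent background to a feature table.

    Salt ladders are ≥3 features spaced by exactly one sodium-formate unit
    (67.98742 Da); they adhere to SMALPs and are therefore rendered enriched,
    so the censoring stage (not the enrichment filter) must remove them.
    Solvent ions appear in sample and control channels at comparable
    intensity (ratio within [0.5, 2]) and fall to the enrichment filter.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng((seed, 0xC0))
    out = list(features)
    counter = max((int(f.feature_id[1:]) for f in features), default=0)

    def emit(mz: float, rt: float, sample: np.ndarray, control: np.ndarray, role: str) -> None:
        nonlocal counter
        counter += 1
        fid = f"F{counter:05d}"
        out.append(
            Feature(
                feature_id=fid,
                mz=round(mz, 6),
                rt=round(rt, 4),
                sample_intensities=tuple(np.round(sample, 2)),
                control_intensities=tuple(np.round(control, 2)),
            )
        )
        if registry is not None:
            registry[fid] = {"role": role, "parent": None, "species": None}

    for _ in range(n_salt_ladders):
        # formate anion + n sodium-formate units; rungs share a retention time
        n_units = rng.integers(4, 8)
        base = 44.998203 + rng.integers(4, 8) * SODIUM_FORMATE_MASS
        rt = rng.uniform(0.5, 2.0)
        level = 10 ** rng.uniform(4.0, 5.5)
        for k in range(int(n_units)):
            s = level * _lognormal_factors(rng, cfg.noise_cv, cfg.n_replicates)
            c = (level / 50.0) * _lognormal_factors(rng, cfg.noise_cv, cfg.control_channels)
            emit(base + k * SODIUM_FORMATE_MASS, rt, s, c, "salt")
            level *= 0.8

    for _ in range(n_solvent):
        mz = rng.uniform(250.0, 1200.0)
        mz = math.floor(mz) + rng.uniform(0.25, 0.95)  # organic-like mass defect
        rt = rng.uniform(0.5, cfg.gradient_span_min - 0.5)
        level = 10 ** rng.uniform(4.0, 5.5)
        ratio = rng.uniform(0.7, 1.4)
        s = level * ratio * _lognormal_factors(rng, cfg.noise_cv, cfg.n_replicates)
        c = level * _lognormal_factors(rng, cfg.noise_cv, cfg.control_channels)
        emit(mz, rt, s, c, "solvent")

    return out


def simulate_experiment(
    seed: int,
    n_species: int = 50,
    cfg: SimConfig | None = None,
    composition: Mapping[LipidClass, float] | None = None,
    n_salt_ladders: int = 4,
    n_solvent: int = 12,
) -> tuple[list[Feature], GroundTruth]:
    """Full synthetic experiment: ground truth → features → contaminants."""
    cfg = cfg or SimConfig()
    truth = generate_ground_truth(seed, n_species, composition)
    features = render_features(truth, cfg)
    features = add_contaminants(
        features, seed, n_salt_ladders, n_solvent, cfg, registry=truth.registry
    )
    return features, truth


def simulate_standard_series(
    kind: str,
    true_endogenous: float,
    slope: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    grid: Sequence[float] | None = None,
    analyte: str = "standard",
    intercept: float = 0.0,
) -> StandardSeries:
    """Simulate a calibration series.

    External series respond only to the spike grid; addition series add the
    endogenous signal to every point.  The default grid is the phospholipid
    spike series (0, 0.5, 1.0, 1.5, 2.0 pmol/µl); pass
    :data:`~perilipid.quant.ERGOSTEROL_SPIKE_GRID` for the sterol series.
    """
    if slope <= 0:
        raise ValueError("response slope must be positive")
    if noise_cv < 0:
        raise ValueError("noise CV must be non-negative")
    if kind not in ("external", "addition"):
        raise ValueError(f"unknown series kind {kind!r}")
    grid = tuple(grid if grid is not None else PHOSPHOLIPID_SPIKE_GRID)
    rng = np.random.default_rng((seed, 0xCA1))
    offset = true_endogenous if kind == "addition" else 0.0
    areas = []
    for x in grid:
        area = slope * (x + offset) + intercept
        area *= _lognormal_factors(rng, noise_cv, 1)[0]
        areas.append(float(area))
    return StandardSeries(
        analyte=analyte, concentrations=grid, areas=tuple(areas), kind=kind
    )


def evaluate_filter_run(events, truth: GroundTruth) -> dict[str, float]:
    """Score a filtering run against the planted ground truth.

    Sensitivity: fraction of true species whose primary feature survives
    inside some event (as representative or collapsed member).  Leakage:
    fraction of surviving events that contain no true-species feature at all
    (pure artifacts or background that escaped the filters).
    """
    species_ids = truth.ids_with_role("species")
    surviving_ids: set[str] = set()
    artifact_events = 0
    for e in events:
        ids = set(e.all_ids)
        surviving_ids |= ids
        if not (ids & species_ids):
            artifact_events += 1
    recovered = len(species_ids & surviving_ids)
    n_events = len(events)
    return {
        "n_true_species": len(species_ids),
        "n_events": n_events,
        "sensitivity": recovered / len(species_ids) if species_ids else float("nan"),
        "artifact_leakage": artifact_events / n_events if n_events else 0.0,
    }


# ---------------------------------------------------------------------------
# feature-table serialization


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    """Feature list → CSV-shaped DataFrame (sample_*/control_* columns)."""
    if not features:
        return pd.DataFrame(columns=["feature_id", "mz", "rt_min"])
    n_s = len(features[0].sample_intensities)
    n_c = len(features[0].control_intensities)
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt}
        row.update({f"sample_{i+1}": v for i, v in enumerate(f.sample_intensities)})
        row.update({f"control_{i+1}": v for i, v in enumerate(f.control_intensities)})
        rows.append(row)
    cols = (
        ["feature_id", "mz", "rt_min"]
        + [f"sample_{i+1}" for i in range(n_s)]
        + [f"control_{i+1}" for i in range(n_c)]
    )
    return pd.DataFrame(rows, columns=cols)


def frame_to_features(frame: pd.DataFrame) -> list[Feature]:
    """CSV-shaped DataFrame → feature list (inverse of features_to_frame)."""
    sample_cols = sorted(
        (c for c in frame.columns if c.startswith("sample_")),
        key=lambda c: int(c.split("_")[1]),
    )
    control_cols = sorted(
        (c for c in frame.columns if c.startswith("control_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return [
        Feature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            rt=float(row["rt_min"]),
            sample_intensities=tuple(float(row[c]) for c in sample_cols),
            control_intensities=tuple(float(row[c]) for c in control_cols),
        )
        for _, row in frame.iterrows()
    ]


def write_feature_table(features: Sequence[Feature], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar JSON used by test oracles."""
    payload = {
        "seed": truth.seed,
        "species": [
            {
                "class": sp.lipid_class.value,
                "carbons": sp.carbons,
                "double_bonds": sp.double_bonds,
                "pmol": pmol,
            }
            for sp, pmol in truth.species
        ],
        "registry": truth.registry,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# toy membrane structures for the geometry code


def synthetic_ring_structure(
    radius: float = 15.0,
    n_atoms: int = 720,
    planes: tuple[float, float] = (15.0, -15.0),
    label: str = "synthetic-ring",
) -> MembraneStructure:
    """Synthetic structure whose leaflet cross-section is a perfect circle.

    ``n_atoms`` carbon atoms on a circle of ``radius`` at each leaflet plane
    (plus a central column between the planes), giving the wedge integrator
    an analytically known footprint of π·radius².
    """
    z_outer, z_inner = planes
    theta = np.linspace(0.0, 2.0 * math.pi, n_atoms, endpoint=False)
    coords = []
    for z in (z_outer, z_inner):
        ring = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.full(n_atoms, z)]
        )
        coords.append(ring)
    column = np.column_stack(
        [np.zeros(9), np.zeros(9), np.linspace(z_inner, z_outer, 9)]
    )
    coords.append(column)
    coords = np.vstack(coords)
    return MembraneStructure(
        elements=np.full(len(coords), "C"),
        coords=coords,
        z_outer=z_outer,
        z_inner=z_inner,
        label=label,
    )


def _elliptical_slab(
    a: float, b: float, z: float, n_atoms: int = 360
) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n_atoms, endpoint=False)
    return np.column_stack(
        [a * np.cos(theta), b * np.sin(theta), np.full(n_atoms, z)]
    )


def synthetic_transporter_conformers(
    planes: tuple[float, float] = (15.0, -15.0),
) -> tuple[MembraneStructure, MembraneStructure]:
    """Synthetic stand-in for an APC-superfamily transporter conformer pair.

    SYNTHETIC: these are not experimental coordinates.  The pair emulates an
    alternating-access transporter at the scale of a 12-helix amino-acid
    permease: on the inward → outward transition the extracellular (outer-
    leaflet) face widens while the cytoplasmic (inner-leaflet) face narrows.
    Leaflet-plane cross-sections are elliptical footprints with areas in the
    1500–1850 Ų range typical of such transporters.  Returns
    (inward, outward).
    """
    z_outer, z_inner = planes
    # (semi-axis a, semi-axis b) per leaflet; area = πab
    geometry = {
        "inward": {"outer": (25.0, 21.41), "inner": (24.0, 22.93)},
        "outward": {"outer": (26.0, 22.32), "inner": (23.0, 21.97)},
    }
    structures = []
    for label in ("inward", "outward"):
        parts = []
        for leaflet, z in (("outer", z_outer), ("inner", z_inner)):
            a, b = geometry[label][leaflet]
            parts.append(_elliptical_slab(a, b, z))
        parts.append(
            np.column_stack(
                [np.zeros(11), np.zeros(11), np.linspace(z_inner, z_outer, 11)]
            )
        )
        coords = np.vstack(parts)
        structures.append(
            MembraneStructure(
                elements=np.full(len(coords), "C"),
                coords=coords,
                z_outer=z_outer,
                z_inner=z_inner,
                label=f"synthetic-transporter-{label}",
            )
        )
    return structures[0], structures[1]


def write_membrane_pdb(structure: MembraneStructure, path: str | Path) -> None:
    """Write a structure as a PDB file with OPM-style DUM leaflet markers."""
    lines = []
    serial = 0
    for element, (x, y, z) in zip(structure.elements, structure.coords):
        serial += 1
        name = element[:2].upper().rjust(2) + "  "
        lines.append(
            f"ATOM  {serial:5d} {name[:4]} GLY A{(serial - 1) % 9999 + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )
    for z in (structure.z_outer, structure.z_inner):
        for x in (-30.0, 30.0):
            for y in (-30.0, 30.0):
                serial += 1
                lines.append(
                    f"HETATM{serial:5d}  N   DUM B{(serial - 1) % 9999 + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           N"
                )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
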