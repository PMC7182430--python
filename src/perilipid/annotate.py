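"""Homolog-series grouping and accurate-mass identification.

After deduplication, molecular events that share an underlying structure
differ only by chain length (CH2 steps) and unsaturation (H2 steps).
Plotting events by retention time and mass exposes these ladders; here they
are recovered as connected components of a graph whose edges are mass
differences of the form k×CH2 + j×H2 consistent with the reversed-phase
elution order.  Kendrick coordinates (mass rescaled by 14/14.01565 so CH2
homologs share a mass defect) are provided for the same purpose.

Identification matches each event's m/z against the theoretical library
within a ppm tolerance; only accurate mass and ionization mode are used, so
isobaric candidates are reported as ambiguous rather than resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .chem import CH2_MASS, H2_MASS, LipidClass
from .filtering import MolecularEvent

__all__ = [
    "SeriesGroup",
    "Annotation",
    "CLASS_PRIORITY",
    "kendrick_coordinates",
    "group_series",
    "identify_species",
    "targeted_search",
    "annotations_frame",
]

#: tie-break priority for ambiguous identifications, most abundant class first
CLASS_PRIORITY: tuple[LipidClass, ...] = (
    LipidClass.PC,
    LipidClass.PE,
    LipidClass.PS,
    LipidClass.PI,
    LipidClass.PG,
    LipidClass.PA,
    LipidClass.CL,
    LipidClass.DAG,
    LipidClass.IPC,
    LipidClass.MIPC,
    LipidClass.ERG,
)


def kendrick_coordinates(mz: float) -> tuple[float, float]:
    """Kendrick mass and Kendrick mass defect for the CH2 base unit.

    KM = mz × 14 / 14.015650; KMD = KM − floor(KM).  CH2 homologs share the
    same KMD exactly; one H2 (unsaturation) step shifts it by 0.013399.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    km = mz * 14.0 / CH2_MASS
    return km, km - math.floor(km)


@dataclass
class SeriesGroup:
    """A connected family of events related by CH2/H2 ladder steps."""

    member_ids: list[str]
    base_id: str
    ladder_steps: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.member_ids)


def _ladder_step(
    delta: float, tol: float, max_ch2: int = 10, max_h2: int = 6
) -> tuple[int, int] | None:
    """Decompose a positive mass difference as k×CH2 + j×H2 within tol."""
    best = None
    for k in range(0, max_ch2 + 1):
        for j in range(-max_h2, max_h2 + 1):
            if k == 0 and j <= 0:
                continue  # require a positive combination toward higher mass
            target = k * CH2_MASS + j * H2_MASS
            if target <= 0:
                continue
            err = abs(delta - target)
            if err <= tol and (best is None or err < best[0]):
                best = (err, k, j)
    return None if best is None else (best[1], best[2])


def group_series(
    events: Sequence[MolecularEvent],
    mz_tol_ppm: float = 5.0,
    rt_window: float = 0.5,
) -> list[SeriesGroup]:
    """Partition events into homolog series via CH2/H2 ladder connectivity.

    An edge joins two events when their mass difference decomposes as
    k×CH2 + j×H2 (k ≥ 0, (k, j) ≠ (0, 0)) within the ppm tolerance and,
    for k > 0, the heavier homolog does not elute earlier than the lighter
    one by more than ``rt_window`` minutes (reversed-phase order).  Connected
    components are returned; every event belongs to exactly one group.
    """
    graph = nx.Graph()
    by_id = {}
    for e in events:
        eid = e.representative.feature_id
        by_id[eid] = e
        graph.add_node(eid)
    order = sorted(events, key=lambda e: e.mz)
    steps: dict[tuple[str, str], tuple[int, int]] = {}
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            delta = b.mz - a.mz
            if delta > 10 * CH2_MASS + 6 * H2_MASS + 1:
                break
            tol = mz_tol_ppm * 1e-6 * b.mz
            step = _ladder_step(delta, tol)
            if step is None:
                continue
            k, _j = step
            if k > 0 and b.rt < a.rt - rt_window:
                continue  # heavier chain eluting much earlier: not a homolog
            a_id = a.representative.feature_id
            b_id = b.representative.feature_id
            graph.add_edge(a_id, b_id)
            steps[(a_id, b_id)] = step
    groups = []
    for comp in nx.connected_components(graph):
        ids = sorted(comp, key=lambda eid: by_id[eid].mz)
        ladder = {pair: s for pair, s in steps.items() if pair[0] in comp}
        groups.append(SeriesGroup(member_ids=ids, base_id=ids[0], ladder_steps=ladder))
    groups.sort(key=lambda g: by_id[g.base_id].mz)
    return groups


@dataclass
class Annotation:
    """Identification result for one molecular event."""

    event_id: str
    status: str  # identified | ambiguous | unidentified
    lipid_class: str | None = None
    carbons: int | None = None
    double_bonds: int | None = None
    adduct: str | None = None
    ppm: float | None = None
    candidates: list[dict] = field(default_factory=list)


def identify_species(
    events: Sequence[MolecularEvent],
    library: pd.DataFrame,
    mz_tol_ppm: float = 5.0,
) -> list[Annotation]:
    """Match events to the theoretical library by accurate mass.

    The candidate with the smallest absolute ppm error wins; candidates tied
    at the same error (isobars) make the event ambiguous, with the reported
    assignment chosen by descending class abundance priority.
    """
    if library.empty:
        raise ValueError("empty library")
    lib = library.sort_values("mz").reset_index(drop=True)
    mzs = lib["mz"].to_numpy()
    prio = {cls.value: i for i, cls in enumerate(CLASS_PRIORITY)}
    out = []
    for e in events:
        eid = e.representative.feature_id
        tol = mz_tol_ppm * 1e-6 * e.mz
        lo = mzs.searchsorted(e.mz - tol, side="left")
        hi = mzs.searchsorted(e.mz + tol, side="right")
        cands = lib.iloc[lo:hi]
        if cands.empty:
            out.append(Annotation(event_id=eid, status="unidentified"))
            continue
        ppms = 1e6 * (e.mz - cands["mz"]) / cands["mz"]
        abs_ppm = ppms.abs()
        best_err = abs_ppm.min()
        # isobars: identical formulas under different class labels tie exactly
        tied = cands[abs_ppm <= best_err + 1e-4]
        tied = tied.assign(_prio=tied["class"].map(prio)).sort_values("_prio")
        top = tied.iloc[0]
        status = "identified" if len(tied) == 1 else "ambiguous"
        out.append(
            Annotation(
                event_id=eid,
                status=status,
                lipid_class=top["class"],
                carbons=int(top["carbons"]),
                double_bonds=int(top["double_bonds"]),
                adduct=top["adduct"],
                ppm=float(1e6 * (e.mz - top["mz"]) / top["mz"]),
                candidates=[
                    {
                        "class": r["class"],
                        "carbons": int(r["carbons"]),
                        "double_bonds": int(r["double_bonds"]),
                        "adduct": r["adduct"],
                        "ppm": float(1e6 * (e.mz - r["mz"]) / r["mz"]),
                    }
                    for _, r in tied.drop(columns="_prio").iterrows()
                ],
            )
        )
    return out


def targeted_search(
    features: Sequence,
    targets: Sequence[tuple[str, float]],
    mz_tol_ppm: float = 20.0,
) -> dict[str, list]:
    """Rescue low-intensity ions by a user-supplied target m/z list.

    Emulates manual examination of ion chromatograms for molecules (e.g.
    sphingolipids) missed by automated peak picking: every feature within the
    (wider) tolerance of a target m/z is reported under that target's label,
    regardless of intensity.
    """
    hits: dict[str, list] = {label: [] for label, _ in targets}
    for f in features:
        for label, target_mz in targets:
            if abs(f.mz - target_mz) <= mz_tol_ppm * 1e-6 * target_mz:
                hits[label].append(f)
    return hits


def annotations_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Flatten annotations to the CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "event_id": a.event_id,
                "class": a.lipid_class,
                "carbons": a.carbons,
                "double_bonds": a.double_bonds,
                "adduct": a.adduct,
                "ppm": a.ppm,
                "status": a.status,
            }
            for a in annotations
        ]
    )
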