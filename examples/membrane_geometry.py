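"""Nanodisc lipid capacity and conformational lipid displacement.

Two geometry estimates: (1) how many lipids fit in a SMALP nanodisc around
one membrane protein (disc area minus polymer rim and protein
cross-section, both leaflets); (2) how many lipids a transporter displaces
per leaflet when it switches conformation, from wedge-integrated leaflet
cross-sections of a membrane-positioned structure pair.  The conformer pair
here is synthetic (no experimental coordinates), built at the scale of a
12-helix amino-acid permease.
"""

from perilipid.geometry import (
    GeometryParams,
    conformational_lipid_delta,
    leaflet_footprint,
    smalp_lipid_capacity,
)
from perilipid.simulate import synthetic_transporter_conformers

params = GeometryParams()
print(
    f"SMALP capacity: {smalp_lipid_capacity(params)} lipids "
    f"(disc {params.smalp_diameter_nm} nm, rim {params.sma_rim_nm} nm, "
    f"protein {params.protein_area_nm2} nm², {params.area_per_lipid / 100:.3f} nm²/lipid)"
)
print("predicted protein:lipid stoichiometry envelope: 1:60–120\n")

inward, outward = synthetic_transporter_conformers()
footprints = {}
for label, structure in (("inward", inward), ("outward", outward)):
    fps = tuple(leaflet_footprint(structure, lf, params) for lf in ("outer", "inner"))
    footprints[label] = fps
    for fp in fps:
        print(
            f"{label:>8} {fp.leaflet:>5} leaflet: footprint {fp.area:7.1f} Ų, "
            f"{fp.lipid_count} lipids within {fp.circle_radius:.0f} Å"
        )

delta = conformational_lipid_delta(footprints["inward"], footprints["outward"])
print(
    f"\ninward → outward displacement: inner {delta['inner']:+d} lipids, "
    f"outer {delta['outer']:+d} lipids"
)
print("a few lipids per leaflet must yield or backfill during the transport cycle")
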