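"""Quantify ER-mitochondria contact sites from traced geometry.

Builds a traced EM-style scene (mitochondrial outlines as polygons, ER
tubules as polylines at programmed stand-off distances, all in nm),
extracts contacts under the 60 nm rule, and prints per-contact GAP and
length, the GAP-bin composition, and the per-cell coverage summary.
"""

from mitoquant.contacts import bin_gaps, extract_contacts, summarize
from mitoquant.synthetic import EMSceneSpec, gen_em_scene

scene = gen_em_scene(
    EMSceneSpec(
        n_mito=3,
        mito_radius_nm=400.0,
        er_segments=(
            (0, 10.0, 300.0),   # tight contact
            (0, 40.0, 500.0),   # wide-gap contact on the same mitochondrion
            (1, 25.0, 400.0),
            (2, 100.0, 400.0),  # beyond 60 nm: not a contact
        ),
        seed=5,
    )
).scene

contacts = extract_contacts(scene, step_nm=5.0)
for c in contacts:
    print(
        f"contact {c.contact_id}: mito {c.mito_id}, length {c.length_nm:6.1f} nm, "
        f"GAP {c.gap_nm:5.1f} nm, bin {c.gap_bin}"
    )
print("GAP bins:", bin_gaps(contacts))

summary = summarize(contacts, scene)
print(
    f"contacts/mito {summary.contacts_per_mito:.2f}, "
    f"mean length {summary.mean_contact_length_nm:.0f} nm, "
    f"mean perimeter {summary.mean_mito_perimeter_nm:.0f} nm, "
    f"coverage {summary.percent_perimeter_covered:.1f}%"
)
print(
    "\nCoverage is the union of contact footprints projected onto the "
    "mitochondrial outlines,\nas a percentage of total perimeter; the "
    "100 nm stand-off segment is correctly excluded."
)
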