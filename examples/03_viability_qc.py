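"""Viability-plate QC: background subtraction and CoV well rejection.

Simulates a resazurin-style plate (5 technical replicates, no-cell
background wells) with two deliberately corrupted wells, then shows that
the QC procedure drops exactly those wells and accepts the rest.
"""

import hipptox as h

cfg = h.SimulationConfig(
    n_chemicals_per_class={"pulmonotoxic": 2, "non_pulmonotoxic": 2, "test": 0},
    n_features=2,
    nc_chemical_ids=("tox_01",),
    seed=3,
)
contamination = {
    "outliers": [
        ("ntx_01", 250.0, 1, 8.0),  # one treated well blown up 8x
        ("ntx_02", 0.0, 3, 7.0),    # one solvent-control well blown up 7x
    ]
}
plate = h.simulate_viability_plate(cfg, contamination=contamination)
reports = h.viability_qc(plate)

for chem, rep in sorted(reports.items()):
    dropped = [w for g in [rep.control] + rep.per_concentration for w in g.dropped_wells]
    print(f"{chem}: verdict={rep.verdict}, "
          f"passing concentrations={rep.n_passing_concentrations}, "
          f"dropped wells={dropped or 'none'}")
print(
    "\nonly the two injected wells are rejected; groups with CoV < 30% "
    "keep all five replicates. NC chemicals keep high-CoV groups whose "
    "median is < 20% of control (heterogeneous cell death)."
)
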