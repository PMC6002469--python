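"""Simulate a small screening study and fit the Δmax matrix.

Generates well-level feature medians for 6 reference chemicals with a
known dose–response structure, fits the candidate concentration–response
models per (chemical, feature), selects by AIC and prints the resulting
maximum-response (Δmax) matrix. Values are log2 treated/control ratios
at 2000 µM (the cell_count row is a control-relative fraction).
"""

import hipptox as h

cfg = h.SimulationConfig(
    n_chemicals_per_class={"pulmonotoxic": 3, "non_pulmonotoxic": 3, "test": 0},
    n_features=5,
    noise_sd=0.1,
    nc_chemical_ids=("tox_01",),
    seed=42,
)
wells, annotations, truth = h.simulate_study(cfg)
print(f"simulated {len(wells)} well records for {len(annotations)} chemicals")

matrix, report = h.build_delta_matrix(wells, annotations)
print("\nΔmax matrix (features × chemicals):")
print(matrix.to_frame().round(3).to_string())

kinds = {}
for kind in report.selected_kind.values():
    kinds[kind.value] = kinds.get(kind.value, 0) + 1
print("\nselected models per (chemical, feature):", kinds)
print(
    "feat_001 is the planted discriminative feature: its Δmax is high for "
    "tox_* chemicals (log2 effect ≈ 1.5) and near zero for ntx_*."
)
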