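"""Autofluorescence QC with the foreground-to-background ratio (FBR).

FBR = log2(99.9th-percentile foreground / median background pixel
intensity). A chemical passes a channel when its FBR is at most 1/3 of
the positive-control FBR for that channel.
"""

import hipptox as h

control_fbr = 3.6  # positive-control stain, green channel

for seed, (chem, target) in enumerate(
    [("clean_chem", 0.2), ("borderline", 1.2), ("autofluor", 2.5)]
):
    fore, back = h.simulate_autofluorescence_pixels(target, seed=seed)
    fbr = h.median_fbr([h.compute_fbr(fore, back) for _ in range(4)])
    res = h.fbr_acceptance(fbr, control_fbr, chemical_id=chem, channel="green")
    print(f"{chem}: FBR = {res.fbr:.2f} log2, threshold = {res.threshold:.2f} "
          f"-> {'pass' if res.passed else 'FAIL'}")
print(
    "\nchemicals failing a channel must be stained/imaged in another "
    "channel whose autofluorescence is acceptable."
)
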