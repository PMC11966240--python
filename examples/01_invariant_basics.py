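"""Compute the backbone rigid invariant (BRI) and its average (Brain).

Builds a small ideal helix, computes the m x 9 invariant and the
9-coordinate Brain vector, then shows that an arbitrary rotation +
translation of the coordinates leaves both unchanged.
"""

import numpy as np

from dupscan import RigidMotion, bri_distance, compute_brain, compute_bri, generate_backbone

chain = generate_backbone(12, seed=1, entry_id="demo")
bri = compute_bri(chain)
brain = compute_brain(bri)

print(f"chain {chain.label}: m = {chain.m} residues")
print(f"BRI shape: {bri.entries.shape}")
print("row 1 (residue 1 in its own frame, the canonical zero pattern):")
print(" ", np.round(bri.entries[0], 4))
print("row 2 (residue 2's N/CA/C in residue 1's frame):")
print(" ", np.round(bri.entries[1], 4))
print("Brain (column means, Å):")
print(" ", np.round(brain.entries, 4))

rng = np.random.default_rng(0)
moved = chain.with_coords(RigidMotion.random(rng).apply(chain.atoms()))
d = bri_distance(bri, compute_bri(moved))
print(f"\nBRI change under a random rigid motion: {d:.2e} Å")
print("-> the invariant is unchanged (numerical noise only); coordinate")
print("   relabeling or rigid-motion disguise cannot hide a duplicate.")
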