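"""Per-residue interaction scores and two-angle water classification.

Runs the canned worked-example trajectory: one residue binds a single water
in every frame, another binds two waters in half the frames.  Both residues
get an interaction score of 1.0 — the mean number of simultaneously bound
waters (1.0 vs 2.0) tells them apart.  The two-reference-angle descriptor of
each contact is also printed.
"""

from aquanet import angle_records, build_network, interaction_scores
from aquanet.fixtures import interaction_demo_frames

networks = [build_network(f) for f in interaction_demo_frames(10)]

print("residue site       raw  score  mean simultaneous")
for r in interaction_scores(networks):
    site = "backbone" if r.backbone_score > 0 else "side-chain"
    print(f"{r.residue_name:>7s} {site:<10s} {r.raw_count:>4d}  {r.score:.2f}"
          f"   {r.mean_simultaneous:.1f}")

angles = angle_records(networks)
print("\nfirst few two-angle records (angles at the water oxygen toward the "
      "default references (0,10,0) and (10,0,10)):")
print(angles.head(4).to_string(index=False,
                               float_format=lambda v: f"{v:.1f}"))
print("Identical (angle1, angle2) pairs across frames mean the water occupies "
      "one well-defined position relative to the protein frame.")
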