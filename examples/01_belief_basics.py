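"""Belief functions over verb forms: frames, similarity and combination.

Builds a two-verb frame, inspects a few mass assignments, and shows how one
round of weighted-evidential social learning moves an undecided agent toward
a committed partner.
"""

from beliefgame import (
    BeliefFunction,
    cosine_similarity,
    make_frame,
    map_reliability,
    social_learn,
)

frame = make_frame(2)
print(f"frame elements: {frame.elements}  ({frame.n_subsets} subsets incl. empty)")

undecided = BeliefFunction.from_dict(frame, {"R1": 0.4, "I1": 0.4, "R1+I1": 0.2})
committed = BeliefFunction.from_dict(frame, {"R1": 1.0})

s = cosine_similarity(undecided, committed)
r = map_reliability(s)
print(f"cosine similarity undecided vs committed: {s:.4f}")
print(f"mapped reliability (fair scale):          {r:.4f}")

# the committed partner speaks with weight 0.5 (its degree share)
updated = social_learn(undecided, [(committed, 0.5, r)])
print("after one social-learning fold:")
for label, mass in updated.to_dict().items():
    print(f"  m({label}) = {mass:.4f}")
print(
    "The regular form R1 gained mass at the expense of I1: agreeing mass\n"
    "products reinforce, conflicting products are discarded by renormalization."
)
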