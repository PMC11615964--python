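"""Self-learning drives regularization.

With learning rate alpha = 5%, lowering the social-learning share p_s gives
agents more solo practice that reinforces regular forms; the regularized
fraction rho_R climbs accordingly.
"""

from beliefgame import SimulationConfig, make_ba, replicate

print(f"{'p_s':>5} {'rho_R':>7} {'R':>7}")
for p_s in (1.0, 0.9, 0.8):
    cfg = SimulationConfig(seed=42, alpha=0.05, p_s=p_s)
    m = replicate(lambda rng: make_ba(100, 5, rng), cfg, n_reps=5).mean()
    print(f"{p_s:5.1f} {m.rho_R:7.3f} {m.R:+7.3f}")
print(
    "\nrho_R climbs as p_s drops: biased solo practice regularizes the\n"
    "lexicon, and the shared attractor (everyone drifting regular-ward) also\n"
    "helps the population agree."
)
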