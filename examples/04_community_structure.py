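"""Community structure: local versus global consensus.

On graphs with known communities (the karate-club factions, LFR benchmarks)
the community-local belief index r runs ahead of the global index R:
communities agree internally while disagreeing with each other.
"""

from beliefgame import SimulationConfig, load_fixture, make_lfr, replicate

cfg = SimulationConfig(seed=42)

karate = replicate(load_fixture("karate"), cfg, n_reps=10).mean()
print(f"karate club : R = {karate.R:+.3f}   local r = {karate.r_local:.3f}")

lfr = replicate(
    lambda rng: make_lfr(100, 3, 1.1, 0.1, 10, 50, 30, 50, rng), cfg, n_reps=10
).mean()
print(f"LFR 3 comms : R = {lfr.R:+.3f}   local r = {lfr.r_local:.3f}")

print(
    "\nr > R in both cases: within a community agents converge on a shared\n"
    "form, but different communities can settle on different forms, holding\n"
    "the global index down."
)
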