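"""How network topology shapes consensus: WS vs ER vs BA.

Replicates the default dynamics on three synthetic families at matched
density and prints the average stabilized observables.  Heterogeneous (hubby)
networks coordinate far better than clustered small-world rings.
"""

from beliefgame import SimulationConfig, make_ba, make_er, make_ws, replicate

N_REPS = 10  # increase for tighter averages
cfg = SimulationConfig(seed=42)

families = {
    "WS(k=10, pr=0.1)": lambda rng: make_ws(100, 10, 0.1, rng),
    "ER(p=0.1)": lambda rng: make_er(100, 0.1, rng),
    "BA(ne=5)": lambda rng: make_ba(100, 5, rng),
}

print(f"{'family':<18} {'L1':>6} {'R':>7} {'rho_R':>6}")
for name, mk in families.items():
    m = replicate(mk, cfg, n_reps=N_REPS).mean()
    print(f"{name:<18} {m.L1:6.3f} {m.R:+7.3f} {m.rho_R:6.3f}")
print(
    "\nL1/R rise from WS to ER to BA: heterogeneity (hubs) promotes consensus,\n"
    "while the clustered ring locks local factions into different conventions."
)
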