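"""Innovation-driven expansion: a four-rung infrastructure ladder.

Each time per-capita fitness falls to the pressure threshold f_min = 0.1
the population adopts the next latent innovation, doubling its capacity
(K = 1, 2, 4, 8).  The phase-plane detector counts the resulting
demographic transitions: inverse-V excursions of growth accompanying a
density gain.
"""

from ismpop import bin_trajectory, detect_transitions, phase_path, run_preset

(traj,) = run_preset("set1_innovation_ladder", seed=0)
print(f"regime switches in the run:  {traj.n_switches}")
print(f"terminal regime / density:   {traj.regime_index[-1]} / {traj.p[-1]:.3f}")

events = detect_transitions(phase_path(bin_trajectory(traj)))
print(f"demographic transitions detected: {len(events)}")
for e in events:
    print(
        f"  bins {e.start:3d}-{e.end:3d}  peak growth {e.growth_at_peak:.3f}"
        f"  density {e.density_start:.3f} -> {e.density_end:.3f}"
    )
# Three switches, three detected transitions: each wave lifts density
# roughly twofold before pressure rebuilds at the next rung.
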