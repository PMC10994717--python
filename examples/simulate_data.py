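"""Generate questionnaire-like longitudinal mixed data with known groups.

Each subject belongs to one of two latent groups whose trajectories on two
latent scales diverge over four visits; observed items (5 continuous + 5
five-level ordinal per scale) load on their scale with unit noise.
"""

from trajconsensus import SimulationConfig, simulate_longitudinal_mixed

cfg = SimulationConfig(n_subjects=50, n_groups=2, seed=1)
ds, truth = simulate_longitudinal_mixed(cfg)

print(ds.data.head(8).to_string(index=False))
print(f"\n{ds.n_subjects} subjects x {cfg.n_visits} visits, "
      f"{len(ds.variables)} variables "
      f"({len(ds.continuous_variables)} continuous, {len(ds.categorical_variables)} ordinal)")
print("true group sizes:", truth.value_counts().sort_index().to_dict())
# The printed rows show one line per subject and visit: a mixed table in
# which the continuous items drift apart between groups as time increases,
# while the ordinal items are the same signal discretized to a 1-5 scale.
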