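"""Mean migration velocity from simulated single-cell trajectories.

For each surface condition, 12 cells are tracked for 30 h at hourly
sampling; per cell, hourly displacements are summed into a cumulative
path length and the velocity is the OLS slope of that curve vs time.
The per-condition summary reports mean +/- SEM over cells.
"""

from dynsurf import SimulationConfig, condition_velocity
from dynsurf.simulate import gen_trajectories

config = SimulationConfig(seed=1)

for condition in (
    "dynamic_linear",
    "dynamic_cyclic",
    "nondynamic_linear_2pct",
    "nondynamic_cyclic_2pct",
):
    trajectories = gen_trajectories(config, condition, n_cells=12)
    _, summary = condition_velocity(trajectories, resample=1.0)
    row = summary.iloc[0]
    print(
        f"{condition:>24s}: {row['mean_velocity_um_hr']:5.1f} "
        f"+/- {row['sem_um_hr']:.1f} um/hr  (n={row['n_cells']})"
    )

# Cells released from patterns onto freshly activated surfaces (dynamic
# conditions) migrate at ~12 um/hr regardless of ligand affinity, while
# cells seeded directly onto the same high-affinity cyclic-RGD chemistry
# (non-dynamic) crawl at ~3 um/hr — the migration-memory contrast.
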