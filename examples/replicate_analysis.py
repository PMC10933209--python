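"""Summarise fC_5 over replicate trajectories of the same system.

Runs three independent seeds of a weakly sticky system, analyses each
replica, and combines them: mean fC_5, sample standard deviation and
the classification from the mean.  Replicate agreement is how one
judges whether a single shorter trajectory suffices for a compound.
"""

from scamscan import (
    SimConfig,
    analyze_series,
    cluster_trajectory,
    recommended_contact_cutoff,
    replicate_summary,
    simulate,
)
from scamscan.trajectory_io import Trajectory

reports = []
for seed in (101, 102, 103):
    config = SimConfig(epsilon=2.0, n_steps=60_000, seed=seed)
    trajectory = simulate(config)
    n_burn = len(trajectory.frames) // 5
    production = Trajectory(trajectory.frames[n_burn:], trajectory.molecule_map)
    series = cluster_trajectory(
        production,
        cutoff=recommended_contact_cutoff(config),
        n_frames=len(production.frames),
    )
    report = analyze_series(series, compound_id="eps=2kT")
    reports.append(report)
    print(f"replica seed {seed}: fC_5 = {report.fc5:5.1f}%  ({report.label})")

summary = replicate_summary(reports)
print()
print(f"mean fC_5 = {summary.fc5_mean:.1f}%  sd = {summary.fc5_sd:.1f}%  "
      f"->  {summary.label}")
print("A standard deviation small against the 20% decision threshold means")
print("the aggregation call is reproducible across replicas.")
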