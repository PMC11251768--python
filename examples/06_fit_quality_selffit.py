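"""Score simulator mean paths against an observed flight (self-fit).

Measured wind-tunnel trajectories can be dropped in as CSV files; here a
simulated flight stands in for the observation, which gives the self-fit
upper bound on agreement.  Four simulator configurations are compared:
with/without the acceleration limit and with/without sensor input noise.
"""

from mothnav.experiments import fit_quality, run_flight_batch

observed = run_flight_batch(1, seed=99)[0].trajectory
report = fit_quality([observed], n_runs=20, seed=0)

print(report["per_pair"][["configuration", "dtw_mae", "r2_raw", "r2"]]
      .to_string(index=False))
print("\ndtw_mae: dynamic-time-warping distance (mean absolute coordinate "
      "error per matched pair, m); r2: variance of the observed path "
      "explained by the simulator's 20-run mean path (clamped at 0).")
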