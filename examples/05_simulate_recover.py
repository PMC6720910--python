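"""Parameter recovery: does refitting the generator's model find its truth?

Simulates a handful of replicate call histories from a known coefficient
vector, rebuilds the panel from the emitted events and refits the model,
then summarizes per-term bias, RMSE and 95% Wald interval coverage.
"""

from noiselag import LatticeSpec, SimulationConfig, make_lattice, parameter_recovery

lattice = make_lattice(LatticeSpec(n_rows=4, n_cols=5, n_districts=4), seed=42)
config = SimulationConfig(n_days=380, seed=42, replicates=5)
result = parameter_recovery(config, lattice=lattice)

table = result.table.set_index("term")
rows = [
    "period[night]", "noisebin1", "noisebin2", "noisebin21",
    "log_inhab", "svi", "botellon",
]
print(f"replicates: {result.n_replicates} (failures: {len(result.failures)})\n")
print(table.loc[rows, ["true", "mean_estimate", "bias", "rmse", "coverage95"]]
      .round(3).to_string())
print(
    "\nEstimates center on the true coefficients and the Wald intervals"
    " cover them; at this small replicate count coverage is coarse — the"
    " calibration check at 100 replicates lives in the test suite."
)
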