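"""Generate a synthetic fertilisation experiment with known nitrogen pools.

Builds the default two-cultivar x five-nitrogen-level x three-replicate
design, writes the four input tables, and shows the true Na gradient the
dataset encodes.
"""

from leafn import DesignConfig, TruthProfile, generate_experiment

config = DesignConfig(seed=42)
dataset = generate_experiment(config, TruthProfile.default(config))
paths = dataset.write("example_output/simulated")

print("tables written:")
for name, path in paths.items():
    print(f"  {name:>10}: {path}")

na = dataset.truth.groupby(["cultivar", "n_level"])["na"].mean().unstack()
print("\ntrue leaf nitrogen Na (g N m-2) by cultivar and applied-N level:")
print(na.round(3).to_string())
print("\nNa rises monotonically with applied N in both cultivars; every sample")
print("carries its exact generating pools in truth.csv for recovery checks.")
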