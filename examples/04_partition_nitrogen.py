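"""Partition one leaf's total nitrogen into the six functional pools.

Inputs: total N per area (Na), fitted Vcmax and Jmax, chlorophyll density
Cc, and measured SDS-insoluble (structural) protein N. Storage N is the
residual, so the pools always sum exactly to Na.
"""

from leafn import LeafSample, partition_sample
from leafn.partition import POOLS

leaf = LeafSample(
    sample_id="leaf-1", na=2.10, vcmax=65.0, jmax=150.0, cc=0.62, n_str=0.36
)
pools = partition_sample(leaf)

print(f"{'pool':<10}{'g N m-2':>10}{'% of Na':>10}")
for pool in POOLS:
    value = getattr(pools, pool)
    print(f"{pool:<10}{value:>10.4f}{100 * pools.fractions[pool]:>9.1f}%")
print(f"{'sum':<10}{sum(getattr(pools, p) for p in POOLS):>10.4f}{100.0:>9.1f}%")
print(f"\nphotosynthetic N (Ncb+Net+Ncl): {pools.n_psn:.4f} g N m-2")
print("storage N is the residual pool; a negative value would be flagged,")
print(f"flags: {pools.flags or 'none'}")
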