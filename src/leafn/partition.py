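"""Functional partitioning of area-based leaf nitrogen.

Total leaf nitrogen Na (g N m-2) is split into four functional pools —
respiratory, photosynthetic, structural and storage — with the
photosynthetic pool further resolved into carboxylation (Rubisco),
electron-transport (cytochrome f) and light-capture (chlorophyll-protein)
subsystems:

    Nresp  = Rt / 33.69,  Rt = 0.015 * Vcmax
    Ncb    = Vcmax / (6.25 * 20.8)
    Net    = Jmax  / (8.06 * 155.6)
    Ncl    = Cc / 2.15
    Npsn   = Ncb + Net + Ncl
    Nstr   = SDS-insoluble protein nitrogen (measured)
    Nstore = Na - Npsn - Nresp - Nstr   (residual)

The residual definition makes the six pools conserve Na exactly. A negative
residual is retained and flagged rather than clipped, so conservation always
holds and inconsistent inputs stay visible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PartitionConstants",
    "LeafSample",
    "NitrogenPools",
    "POOLS",
    "n_resp",
    "n_cb",
    "n_et",
    "n_cl",
    "partition_sample",
    "partition_table",
]

POOLS = ("n_resp", "n_cb", "n_et", "n_cl", "n_str", "n_store")


@dataclass(frozen=True)
class PartitionConstants:
    """Conversion constants linking capacities to nitrogen investments.

    resp_per_gN : respiration supported per g N per s at 25 degC, umol CO2 g-1 N s-1
    resp_fraction_of_vcmax : total respiration as a fraction of Vcmax
    vcr : specific activity of Rubisco, umol CO2 (g Rubisco)-1 s-1
    n_to_protein : g protein per g N
    jmc : maximum electron transport per unit cytochrome f, umol e- (umol Cyt f)-1 s-1
    cytf_per_gN : umol Cyt f per g N
    cb : chlorophyll bound per g light-capture N, mmol (g N)-1
    """

    resp_per_gN: float = 33.69
    resp_fraction_of_vcmax: float = 0.015
    vcr: float = 20.8
    n_to_protein: float = 6.25
    jmc: float = 155.6
    cytf_per_gN: float = 8.06
    cb: float = 2.15

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"partition constant {name} must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


DEFAULT_CONSTANTS = PartitionConstants()


@dataclass
class LeafSample:
    """Merged per-sample inputs for the nitrogen partition."""

    sample_id: str
    na: float  # g N m-2
    vcmax: float = 0.0  # umol m-2 s-1
    jmax: float = 0.0
    cc: float = 0.0  # mmol chlorophyll m-2
    n_str: float = 0.0  # g N m-2, SDS-insoluble protein N
    cultivar: str = ""
    n_level: str = ""
    replicate: str = ""
    asat: float = math.nan
    gsw: float = math.nan
    lma: float = math.nan
    rd: float = math.nan  # fitted Rd, diagnostic only (Nresp uses 0.015*Vcmax)

    def __post_init__(self) -> None:
        if not self.na > 0:
            raise ValueError(f"{self.sample_id}: na must be > 0")
        if self.n_str < 0:
            raise ValueError(f"{self.sample_id}: n_str must be >= 0")
        if self.vcmax < 0 or self.jmax < 0:
            raise ValueError(f"{self.sample_id}: capacities must be >= 0")


@dataclass
class NitrogenPools:
    sample_id: str
    n_resp: float
    n_cb: float
    n_et: float
    n_cl: float
    n_str: float
    n_store: float
    na: float
    flags: list[str] = field(default_factory=list)

    @property
    def n_psn(self) -> float:
        return self.n_cb + self.n_et + self.n_cl

    @property
    def fractions(self) -> dict[str, float]:
        return {pool: getattr(self, pool) / self.na for pool in POOLS}


def _check_nonneg(value: float, name: str) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0")


def n_resp(vcmax: float, constants: PartitionConstants = DEFAULT_CONSTANTS) -> float:
    """Respiratory nitrogen: Rt / resp_per_gN with Rt = 0.015 * Vcmax."""
    _check_nonneg(vcmax, "vcmax")
    rt = constants.resp_fraction_of_vcmax * vcmax
    return rt / constants.resp_per_gN


def n_cb(vcmax: float, constants: PartitionConstants = DEFAULT_CONSTANTS) -> float:
    """Carboxylation-system nitrogen: Vcmax / (6.25 * Vcr)."""
    _check_nonneg(vcmax, "vcmax")
    return vcmax / (constants.n_to_protein * constants.vcr)


def n_et(jmax: float, constants: PartitionConstants = DEFAULT_CONSTANTS) -> float:
    """Electron-transport-system nitrogen: Jmax / (8.06 * Jmc)."""
    _check_nonneg(jmax, "jmax")
    return jmax / (constants.cytf_per_gN * constants.jmc)


def n_cl(cc: float, constants: PartitionConstants = DEFAULT_CONSTANTS) -> float:
    """Light-capture-system nitrogen: Cc / CB."""
    _check_nonneg(cc, "cc")
    return cc / constants.cb


def partition_sample(
    leaf: LeafSample, constants: PartitionConstants = DEFAULT_CONSTANTS
) -> NitrogenPools:
    """Partition one sample's Na into the six pools; storage is the residual."""
    if not leaf.na > 0:
        raise ValueError(f"{leaf.sample_id}: na must be > 0")
    if leaf.n_str < 0:
        raise ValueError(f"{leaf.sample_id}: n_str must be >= 0")
    pools = NitrogenPools(
        sample_id=leaf.sample_id,
        n_resp=n_resp(leaf.vcmax, constants),
        n_cb=n_cb(leaf.vcmax, constants),
        n_et=n_et(leaf.jmax, constants),
        n_cl=n_cl(leaf.cc, constants),
        n_str=leaf.n_str,
        n_store=0.0,
        na=leaf.na,
    )
    pools.n_store = leaf.na - pools.n_psn - pools.n_resp - pools.n_str
    if pools.n_store < 0:
        pools.flags.append("negative-storage")
    return pools


def partition_table(
    samples: list[LeafSample],
    constants: PartitionConstants = DEFAULT_CONSTANTS,
    *,
    meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a list of samples into tidy long pool and fraction tables.

    Returns ``(pools, fractions)``; both are long format, one row per
    sample x pool with ``value`` in g N m-2 (pools) or as a fraction of Na
    (fractions). ``meta`` (indexed or keyed by sample_id) is merged onto both
    for grouping. Per-sample failures are re-raised with the sample_id
    attached.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    pool_rows, frac_rows = [], []
    for leaf in samples:
        try:
            pools = partition_sample(leaf, constants)
        except ValueError as exc:
            raise ValueError(f"sample {leaf.sample_id!r}: {exc}") from exc
        flag_str = ";".join(pools.flags)
        for pool in POOLS:
            pool_rows.append(
                {
                    "sample_id": leaf.sample_id,
                    "cultivar": leaf.cultivar,
                    "n_level": leaf.n_level,
                    "pool": pool,
                    "value": getattr(pools, pool),
                    "na": leaf.na,
                    "flags": flag_str,
                }
            )
            frac_rows.append(
                {
                    "sample_id": leaf.sample_id,
                    "cultivar": leaf.cultivar,
                    "n_level": leaf.n_level,
                    "pool": pool,
                    "fraction": pools.fractions[pool],
                    "flags": flag_str,
                }
            )
    pools_df = pd.DataFrame(pool_rows)
    fracs_df = pd.DataFrame(frac_rows)
    if meta is not None:
        pools_df = pools_df.merge(meta, on="sample_id", how="left")
        fracs_df = fracs_df.merge(meta, on="sample_id", how="left")
    return pools_df, fracs_df


def group_means(long_df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean +/- sd of each pool by cultivar x nitrogen level."""
    return (
        long_df.groupby(["cultivar", "n_level", "pool"], sort=True)[value_col]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
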