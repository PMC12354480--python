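"""Synthetic nitrogen-fertilisation experiment with known ground truth.

Generates, backwards from true nitrogen pools, everything the analysis
pipeline consumes: a leaf-trait table, per-sample A-Ci curves and a
chlorophyll absorbance table, for a two-cultivar x five-nitrogen-level
(N0-N4) x three-replicate pot design. Working backwards means inverting the
partition and pigment equations — true pools define Vcmax, Jmax and the
chlorophyll density, which in turn define the gas-exchange and absorbance
observations — so a noiseless dataset round-trips through the pipeline to
the exact truth, and noisy datasets have a known recovery target.

Default truth profiles encode the fertilisation-response shapes typical of
such trials: Na monotone increasing with applied N; carboxylation and
electron-transport nitrogen peaking at the second-highest level (N3);
light-capture nitrogen rising steadily in one cultivar and peaking then
declining in the other; structural nitrogen near-flat; storage nitrogen
rising convexly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fvcb import DEFAULT_KINETICS, ACiCurve, FvCBParams, KineticConstants, fvcb_assimilation
from .partition import DEFAULT_CONSTANTS, PartitionConstants
from .pigments import CHLA_COEF, CHLB_COEF, DEFAULT_CHL_MOLAR_MASS

__all__ = [
    "DesignConfig",
    "TruthProfile",
    "SyntheticDataset",
    "DEFAULT_CI_LADDER",
    "pools_to_capacities",
    "generate_aci_curve",
    "chlorophyll_to_absorbances",
    "generate_experiment",
]

# Reference-chamber CO2 ladder of the measurement protocol, used directly as
# Ci targets (the fit operates on Ci; modelling stomata is out of scope). The
# three 400s are protocol stability checks kept as replicate observations.
DEFAULT_CI_LADDER = (400.0, 300.0, 200.0, 150.0, 100.0, 50.0, 400.0, 400.0,
                     600.0, 800.0, 1000.0, 1200.0, 1500.0)


@dataclass(frozen=True)
class DesignConfig:
    """Factorial design: cultivars x nitrogen levels x replicates."""

    cultivars: tuple[str, ...] = ("FD", "JF")
    n_levels: tuple[str, ...] = ("N0", "N1", "N2", "N3", "N4")
    applied_n: tuple[float, ...] = (0.0, 220.0, 440.0, 660.0, 880.0)  # kg hm-2
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.n_levels) != len(self.applied_n):
            raise ValueError("n_levels and applied_n must align")
        if len(set(self.n_levels)) != len(self.n_levels):
            raise ValueError("n_levels must be distinct")
        if list(self.applied_n) != sorted(self.applied_n):
            raise ValueError("n_levels must be ordered by applied N")


@dataclass
class PoolTruth:
    """True pool means for one cultivar x level cell (g N m-2) plus LMA (g m-2)."""

    ncb: float
    net: float
    ncl: float
    nstr: float
    nstore: float
    lma: float

    def __post_init__(self) -> None:
        for name in ("ncb", "net", "ncl", "nstr", "lma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"true pool {name} must be > 0")
        if self.nstore < 0:
            raise ValueError("true nstore must be >= 0")


# per-cultivar arrays over N0..N4; shapes described in the module docstring
_DEFAULT_TRUTH = {
    "FD": {
        "ncb": (0.32, 0.42, 0.50, 0.55, 0.48),
        "net": (0.075, 0.095, 0.110, 0.120, 0.105),
        "ncl": (0.24, 0.28, 0.31, 0.29, 0.26),
        "nstr": (0.34, 0.35, 0.36, 0.36, 0.37),
        "nstore": (0.45, 0.55, 0.70, 0.90, 1.20),
        "lma": (55.0, 58.0, 60.0, 62.0, 63.0),
    },
    "JF": {
        "ncb": (0.40, 0.50, 0.57, 0.62, 0.52),
        "net": (0.090, 0.110, 0.125, 0.135, 0.115),
        "ncl": (0.16, 0.19, 0.22, 0.25, 0.27),
        "nstr": (0.38, 0.37, 0.37, 0.38, 0.39),
        "nstore": (0.55, 0.65, 0.80, 1.00, 1.30),
        "lma": (50.0, 54.0, 57.0, 59.0, 60.0),
    },
}


@dataclass
class TruthProfile:
    """Ground-truth pool means per cultivar x level, plus noise magnitudes.

    noise_sd_a : additive sd on every assimilation reading, umol m-2 s-1
    noise_cv_traits : multiplicative cv on measured traits and absorbances
    asat_ci : operating Ci at which the trait-table Asat is generated
    chla_chlb_ratio : a:b split used when mapping chlorophyll to absorbances
    """

    cells: dict[tuple[str, str], PoolTruth]
    noise_sd_a: float = 0.5
    noise_cv_traits: float = 0.03
    asat_ci: float = 280.0
    chla_chlb_ratio: float = 3.0
    chl_molar_mass: float = DEFAULT_CHL_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.noise_sd_a < 0 or self.noise_cv_traits < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def default(cls, config: DesignConfig | None = None, **kwargs) -> "TruthProfile":
        config = config or DesignConfig()
        cells = {}
        for cultivar in config.cultivars:
            prof = _DEFAULT_TRUTH[cultivar]
            for i, level in enumerate(config.n_levels):
                cells[(cultivar, level)] = PoolTruth(
                    ncb=prof["ncb"][i],
                    net=prof["net"][i],
                    ncl=prof["ncl"][i],
                    nstr=prof["nstr"][i],
                    nstore=prof["nstore"][i],
                    lma=prof["lma"][i],
                )
        return cls(cells=cells, **kwargs)

    def zero_noise(self) -> "TruthProfile":
        return TruthProfile(
            cells=dict(self.cells),
            noise_sd_a=0.0,
            noise_cv_traits=0.0,
            asat_ci=self.asat_ci,
            chla_chlb_ratio=self.chla_chlb_ratio,
            chl_molar_mass=self.chl_molar_mass,
        )


def pools_to_capacities(
    ncb: float,
    net: float,
    ncl: float,
    constants: PartitionConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Invert the partition equations: (Vcmax, Jmax, Cc) from pool nitrogen.

    Vcmax = Ncb * 6.25 * Vcr; Jmax = Net * 8.06 * Jmc; Cc = Ncl * CB. The
    forward partition operations reproduce the pools to machine precision.
    """
    for name, value in (("ncb", ncb), ("net", net), ("ncl", ncl)):
        if value < 0:
            raise ValueError(f"pool {name} must be >= 0")
    vcmax = ncb * constants.n_to_protein * constants.vcr
    jmax = net * constants.cytf_per_gN * constants.jmc
    cc = ncl * constants.cb
    return vcmax, jmax, cc


def generate_aci_curve(
    params: FvCBParams,
    kinetics: KineticConstants = DEFAULT_KINETICS,
    ci_ladder=DEFAULT_CI_LADDER,
    noise_sd: float = 0.5,
    seed=None,
    sample_id: str = "synthetic",
) -> ACiCurve:
    """Forward-simulate one A-Ci curve: FvCB model plus i.i.d. Gaussian noise.

    ``seed`` may be an int or a numpy Generator; the same seed gives a
    bitwise-identical curve.
    """
    ci = np.asarray(ci_ladder, dtype=float)
    if ci.size == 0 or np.any(ci <= 0):
        raise ValueError("ci_ladder must be non-empty and positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = fvcb_assimilation(ci, params, kinetics)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=ci.shape)
    return ACiCurve(sample_id=sample_id, ci=ci, a=np.asarray(a, dtype=float))


def chlorophyll_to_absorbances(chla_mg_l: float, chlb_mg_l: float) -> tuple[float, float]:
    """Invert the two-wavelength pigment equations: (A665, A649) for target concentrations.

    Solves the 2x2 linear system; pairs that would need a negative absorbance
    (e.g. extreme a:b ratios) are rejected.
    """
    m = np.array([[CHLA_COEF[0], CHLA_COEF[1]], [CHLB_COEF[0], CHLB_COEF[1]]])
    a665, a649 = np.linalg.solve(m, np.array([chla_mg_l, chlb_mg_l], dtype=float))
    if a665 < -1e-12 or a649 < -1e-12:
        raise ValueError(
            f"chla={chla_mg_l}, chlb={chlb_mg_l} mg/L is infeasible: would require "
            f"negative absorbance (A665={a665:.4g}, A649={a649:.4g})"
        )
    return float(max(a665, 0.0)), float(max(a649, 0.0))


@dataclass
class SyntheticDataset:
    """Generated experiment: observed tables plus the exact truth table."""

    traits: pd.DataFrame
    aci: pd.DataFrame
    absorbance: pd.DataFrame
    truth: pd.DataFrame
    config: DesignConfig = field(repr=False, default=None)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("traits", self.traits),
            ("aci_curves", self.aci),
            ("absorbance", self.absorbance),
            ("truth", self.truth),
        ):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def generate_experiment(
    config: DesignConfig | None = None,
    truth: TruthProfile | None = None,
    constants: PartitionConstants = DEFAULT_CONSTANTS,
    kinetics: KineticConstants = DEFAULT_KINETICS,
    ci_ladder=DEFAULT_CI_LADDER,
) -> SyntheticDataset:
    """Generate the full factorial experiment from ground-truth pools.

    Every sample's truth row carries the exact pools, capacities and traits;
    observed tables add the configured measurement noise (multiplicative on
    traits and absorbances, additive on assimilation).
    """
    config = config or DesignConfig()
    truth = truth or TruthProfile.default(config)
    rng = np.random.default_rng(config.seed)

    trait_rows, aci_rows, abs_rows, truth_rows = [], [], [], []
    mult = lambda x: x * (1.0 + truth.noise_cv_traits * rng.standard_normal())  # noqa: E731

    for cultivar in config.cultivars:
        for level in config.n_levels:
            cell = truth.cells[(cultivar, level)]
            for rep in range(1, config.replicates + 1):
                sid = f"{cultivar}-{level}-r{rep}"
                vcmax, jmax, cc = pools_to_capacities(cell.ncb, cell.net, cell.ncl, constants)
                rd = constants.resp_fraction_of_vcmax * vcmax
                nresp = rd / constants.resp_per_gN
                na = cell.ncb + cell.net + cell.ncl + cell.nstr + cell.nstore + nresp
                params = FvCBParams(vcmax=vcmax, jmax=jmax, rd=rd)
                asat_true = fvcb_assimilation(truth.asat_ci, params, kinetics)

                # chlorophyll: area density -> mass basis -> extract -> absorbances
                chl_mass = cc * truth.chl_molar_mass / cell.lma  # mg/g
                r = truth.chla_chlb_ratio
                conc = chl_mass * 0.2 / 0.025  # mg/L in a 25 mL extract of 0.2 g
                a665, a649 = chlorophyll_to_absorbances(conc * r / (1 + r), conc / (1 + r))

                truth_rows.append(
                    {
                        "sample_id": sid, "cultivar": cultivar, "n_level": level,
                        "replicate": rep, "na": na, "n_resp": nresp, "n_cb": cell.ncb,
                        "n_et": cell.net, "n_cl": cell.ncl, "n_str": cell.nstr,
                        "n_store": cell.nstore, "vcmax": vcmax, "jmax": jmax,
                        "rd": rd, "cc": cc, "lma": cell.lma, "asat": asat_true,
                        "pnue": asat_true / na,
                    }
                )
                asat_obs = asat_true + (
                    rng.normal(0.0, truth.noise_sd_a) if truth.noise_sd_a > 0 else 0.0
                )
                gsw_true = 0.08 + 0.012 * max(asat_true, 0.0)
                trait_rows.append(
                    {
                        "sample_id": sid, "cultivar": cultivar, "n_level": level,
                        "replicate": rep, "na": mult(na), "n_str": mult(cell.nstr),
                        "lma": mult(cell.lma), "asat": asat_obs, "gsw": mult(gsw_true),
                    }
                )
                abs_rows.append(
                    {
                        "sample_id": sid, "a665": mult(a665), "a649": mult(a649),
                        "extract_volume_ml": 25.0, "tissue_mass_g": 0.2,
                    }
                )
                curve = generate_aci_curve(
                    params, kinetics, ci_ladder, truth.noise_sd_a, rng, sample_id=sid
                )
                for step, (ci_val, a_val) in enumerate(zip(curve.ci, curve.a), start=1):
                    aci_rows.append(
                        {
                            "sample_id": sid, "step": step, "ci": ci_val, "a": a_val,
                            "leaf_temp": 25.0, "ppfd": 1000.0,
                        }
                    )

    return SyntheticDataset(
        traits=pd.DataFrame(trait_rows),
        aci=pd.DataFrame(aci_rows),
        absorbance=pd.DataFrame(abs_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
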