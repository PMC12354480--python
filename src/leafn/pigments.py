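"""Chlorophyll quantification from 95%-ethanol extract absorbances.

Concentrations in the extract (mg/L) follow the two-wavelength equations

    Chla = 13.95 A665 - 6.88 A649
    Chlb = 24.96 A649 - 7.32 A665
    Chlt = Chla + Chlb

scaled to a tissue-mass basis by the extraction geometry
(mg/g = mg/L x extract volume / tissue mass; 25 mL on 0.2 g gives 0.125),
and to a leaf-area chlorophyll density Cc (mmol/m2) via leaf mass per area:
Cc = chl[mg/g] x LMA[g/m2] / molar mass[g/mol].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CHLA_COEF",
    "CHLB_COEF",
    "DEFAULT_CHL_MOLAR_MASS",
    "PigmentRecord",
    "ChlorophyllResult",
    "chlorophyll_concentrations",
    "extract_to_mass_basis",
    "chl_area_density",
    "quantify_record",
    "read_absorbances",
    "pigment_table",
]

# (coefficient on A665, coefficient on A649), mg/L per absorbance unit
CHLA_COEF = (13.95, -6.88)
CHLB_COEF = (-7.32, 24.96)

# between chlorophyll a (893.5 g/mol) and b (907.5 g/mol); <1% lever on Cc
DEFAULT_CHL_MOLAR_MASS = 900.0


@dataclass
class PigmentRecord:
    """Absorbances plus extraction geometry for one sample."""

    sample_id: str
    a665: float
    a649: float
    extract_volume: float = 0.025  # L (25 mL volumetric flask)
    tissue_mass: float = 0.2  # g fresh tissue
    path_length: float = 1.0  # cm cuvette

    def __post_init__(self) -> None:
        if self.a665 < 0 or self.a649 < 0:
            raise ValueError(f"{self.sample_id}: absorbances must be >= 0")
        if self.extract_volume <= 0 or self.tissue_mass <= 0:
            raise ValueError(f"{self.sample_id}: extract volume and tissue mass must be > 0")


@dataclass
class ChlorophyllResult:
    sample_id: str
    chla: float  # mg/g
    chlb: float  # mg/g
    chlt: float  # mg/g, identically chla + chlb
    cc: float = math.nan  # mmol/m2, requires LMA
    chla_chlb_ratio: float = math.nan
    warnings: list[str] = field(default_factory=list)


def chlorophyll_concentrations(a665, a649):
    """Extract concentrations (chla, chlb, chlt) in mg/L from absorbances.

    A negative component signals an inconsistent absorbance pair (outside the
    cone the coefficient matrix maps positive concentrations into); it is
    returned as-is, never clipped — callers decide how to flag it.
    """
    a665 = np.asarray(a665, dtype=float)
    a649 = np.asarray(a649, dtype=float)
    if np.any(a665 < 0) or np.any(a649 < 0):
        raise ValueError("absorbances must be >= 0")
    chla = CHLA_COEF[0] * a665 + CHLA_COEF[1] * a649
    chlb = CHLB_COEF[0] * a665 + CHLB_COEF[1] * a649
    chlt = chla + chlb
    if a665.ndim == 0:
        return float(chla), float(chlb), float(chlt)
    return chla, chlb, chlt


def extract_to_mass_basis(conc_mg_per_l, record: PigmentRecord):
    """Convert an extract concentration (mg/L) to tissue mass basis (mg/g)."""
    return np.asarray(conc_mg_per_l, dtype=float) * record.extract_volume / record.tissue_mass


def chl_area_density(chl_mass_basis, lma, molar_mass: float = DEFAULT_CHL_MOLAR_MASS):
    """Leaf-area chlorophyll density Cc (mmol/m2) from mg/g chlorophyll and LMA.

    mg g-1 x g m-2 / (g mol-1) = mmol m-2. Raises when LMA is missing or
    non-positive, because the light-capture nitrogen pool cannot be computed
    without it.
    """
    lma = np.asarray(lma, dtype=float)
    if np.any(~np.isfinite(lma)) or np.any(lma <= 0):
        raise ValueError("LMA must be a positive finite value to compute Cc (mmol/m2)")
    return np.asarray(chl_mass_basis, dtype=float) * lma / molar_mass


def quantify_record(
    record: PigmentRecord,
    lma: float | None = None,
    molar_mass: float = DEFAULT_CHL_MOLAR_MASS,
) -> ChlorophyllResult:
    """Full per-sample chlorophyll quantification (mass basis, ratio, Cc)."""
    chla_l, chlb_l, _ = chlorophyll_concentrations(record.a665, record.a649)
    warn = []
    if chla_l < 0:
        warn.append("negative-chla")
    if chlb_l < 0:
        warn.append("negative-chlb")
    chla = float(extract_to_mass_basis(chla_l, record))
    chlb = float(extract_to_mass_basis(chlb_l, record))
    cc = math.nan
    if lma is not None:
        cc = float(chl_area_density(chla + chlb, lma, molar_mass))
    ratio = chla / chlb if chlb != 0 else math.nan
    return ChlorophyllResult(
        sample_id=record.sample_id,
        chla=chla,
        chlb=chlb,
        chlt=chla + chlb,
        cc=cc,
        chla_chlb_ratio=ratio,
        warnings=warn,
    )


def read_absorbances(path, sep: str = ",") -> list[PigmentRecord]:
    """Read an absorbance table (sample_id, a665, a649[, extract_volume_ml, tissue_mass_g]).

    An ``a645`` column is accepted as an alias for ``a649`` with a logged
    warning (the operative equations are written on A649).
    """
    df = pd.read_csv(path, sep=sep)
    if "a649" not in df.columns and "a645" in df.columns:
        log.warning("%s: column 'a645' used as alias for 'a649'", path)
        df = df.rename(columns={"a645": "a649"})
    missing = [c for c in ("sample_id", "a665", "a649") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        if "extract_volume_ml" in df.columns:
            kwargs["extract_volume"] = float(row["extract_volume_ml"]) / 1000.0
        if "tissue_mass_g" in df.columns:
            kwargs["tissue_mass"] = float(row["tissue_mass_g"])
        records.append(
            PigmentRecord(
                sample_id=str(row["sample_id"]),
                a665=float(row["a665"]),
                a649=float(row["a649"]),
                **kwargs,
            )
        )
    return records


def pigment_table(
    records: list[PigmentRecord],
    lma_by_sample: dict[str, float] | None = None,
    molar_mass: float = DEFAULT_CHL_MOLAR_MASS,
) -> pd.DataFrame:
    """Tabulate chlorophyll results (chla_mg_g, chlb_mg_g, chlt_mg_g, cc_mmol_m2)."""
    rows = []
    for rec in records:
        lma = None if lma_by_sample is None else lma_by_sample.get(rec.sample_id)
        res = quantify_record(rec, lma=lma, molar_mass=molar_mass)
        rows.append(
            {
                "sample_id": res.sample_id,
                "chla_mg_g": res.chla,
                "chlb_mg_g": res.chlb,
                "chlt_mg_g": res.chlt,
                "cc_mmol_m2": res.cc,
                "chla_chlb_ratio": res.chla_chlb_ratio,
                "flags": ";".join(res.warnings),
            }
        )
    return pd.DataFrame(rows)
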