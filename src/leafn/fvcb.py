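"""Farquhar-von Caemmerer-Berry (FvCB) photosynthesis model and A-Ci curve fitting.

The net CO2 assimilation rate of a C3 leaf is modelled as the minimum of a
Rubisco-limited rate ``Ac`` and an RuBP-regeneration-limited rate ``Aj``,
minus day respiration ``Rd``::

    Ac = Vcmax * (Ci - gamma*) / (Ci + Kc * (1 + O / Ko))
    Aj = J     * (Ci - gamma*) / (4 * Ci + 8 * gamma*)
    A  = min(Ac, Aj) - Rd

with ``J = Jmax`` under saturating light (the measurement protocol holds
PPFD at 1000 umol m-2 s-1). ``Vcmax`` and ``Jmax`` are estimated from an
A-Ci response curve by a partitioned-range fit (Rubisco-limited points at
low Ci, RuBP-limited points at high Ci) followed by a joint
limitation-assignment refinement.

All rates are umol m-2 s-1, Ci in umol mol-1, at a leaf temperature of
25 degC; no temperature normalisation is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticConstants",
    "FvCBParams",
    "ACiCurve",
    "FitError",
    "InsufficientSpanError",
    "fvcb_assimilation",
    "rubisco_limited",
    "rubp_limited",
    "transition_ci",
    "fit_aci",
    "read_gas_exchange",
    "params_table",
]


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 degC (tobacco-derived in vivo values).

    kc : Michaelis constant for CO2, umol mol-1
    ko : Michaelis constant for O2, mmol mol-1
    gamma_star : CO2 compensation point without day respiration, umol mol-1
    o : chloroplastic O2 mole fraction, mmol mol-1
    """

    kc: float = 404.9
    ko: float = 278.4
    gamma_star: float = 42.75
    o: float = 210.0

    def __post_init__(self) -> None:
        for name in ("kc", "ko", "gamma_star", "o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic constant {name} must be > 0")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc * (1 + O/Ko), umol mol-1."""
        return self.kc * (1.0 + self.o / self.ko)


DEFAULT_KINETICS = KineticConstants()


@dataclass
class FvCBParams:
    """Fitted (or assumed) FvCB parameters for one leaf at 25 degC."""

    vcmax: float
    jmax: float
    rd: float = 0.0
    transition_ci: float = math.nan
    sse: float = math.nan
    n_points_c: int = 0
    n_points_j: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vcmax <= 0:
            raise ValueError("vcmax must be > 0")
        if self.jmax <= 0:
            raise ValueError("jmax must be > 0")
        if self.rd < 0:
            raise ValueError("rd must be >= 0")
        ratio = self.jmax / self.vcmax
        if not 0.5 <= ratio <= 4.0 and "jmax-vcmax-ratio" not in self.flags:
            # diagnostic only: physiologically unusual but not an error
            self.flags.append("jmax-vcmax-ratio")


@dataclass
class ACiCurve:
    """One sample's A-Ci response: assimilation across an intercellular-CO2 ladder."""

    sample_id: str
    ci: np.ndarray
    a: np.ndarray
    leaf_temp: float = 25.0
    ppfd: float = 1000.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.shape != self.a.shape or self.ci.ndim != 1:
            raise ValueError("ci and a must be 1-d arrays of equal length")
        if np.any(self.ci <= 0):
            raise ValueError("all Ci values must be > 0")
        if len(self.ci) < 6 and "too-few-points" not in self.flags:
            self.flags.append("too-few-points")
        if not np.any(self.ci <= 300.0) and "no-low-ci" not in self.flags:
            self.flags.append("no-low-ci")
        if not np.any(self.ci >= 600.0) and "no-high-ci" not in self.flags:
            self.flags.append("no-high-ci")

    @property
    def is_fittable(self) -> bool:
        return not any(
            f in self.flags for f in ("too-few-points", "no-low-ci", "no-high-ci")
        )

    def __len__(self) -> int:
        return len(self.ci)


class FitError(RuntimeError):
    """A-Ci fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, best: FvCBParams | None = None):
        super().__init__(message)
        self.best = best


class InsufficientSpanError(ValueError):
    """The Ci ladder does not cover a region required for the fit."""


def rubisco_limited(ci, vcmax: float, kinetics: KineticConstants = DEFAULT_KINETICS):
    """Rubisco-limited gross carboxylation rate Ac (no Rd)."""
    ci = np.asarray(ci, dtype=float)
    return vcmax * (ci - kinetics.gamma_star) / (ci + kinetics.km)


def rubp_limited(ci, jmax: float, kinetics: KineticConstants = DEFAULT_KINETICS):
    """RuBP-regeneration-limited gross rate Aj at J = Jmax (no Rd)."""
    ci = np.asarray(ci, dtype=float)
    g = kinetics.gamma_star
    return jmax * (ci - g) / (4.0 * ci + 8.0 * g)


def fvcb_assimilation(ci, params: FvCBParams, kinetics: KineticConstants = DEFAULT_KINETICS):
    """Net assimilation A = min(Ac, Aj) - Rd at the given Ci (scalar or array)."""
    scalar = np.isscalar(ci)
    ci_arr = np.atleast_1d(np.asarray(ci, dtype=float))
    if np.any(ci_arr <= 0):
        raise ValueError("ci must be > 0")
    a = (
        np.minimum(
            rubisco_limited(ci_arr, params.vcmax, kinetics),
            rubp_limited(ci_arr, params.jmax, kinetics),
        )
        - params.rd
    )
    return float(a[0]) if scalar else a


def transition_ci(vcmax: float, jmax: float, kinetics: KineticConstants = DEFAULT_KINETICS) -> float:
    """Ci at which Ac = Aj (closed form); inf when the limbs never cross.

    Solving Vcmax (4 Ci + 8 gamma*) = Jmax (Ci + Km) for Ci.
    """
    den = 4.0 * vcmax - jmax
    if den <= 0:
        return math.inf
    return (jmax * kinetics.km - 8.0 * kinetics.gamma_star * vcmax) / den


def _limb_lstsq(ci, a, limb_c, kinetics, fix_rd: float | None = None):
    """Exact least squares for (vcmax, jmax, rd) given a limb assignment.

    The model is linear in the parameters once each point is assigned to the
    Rubisco or RuBP limb. Returns (vcmax, jmax, rd); parameters whose limb is
    empty come back as nan.
    """
    f = np.asarray(rubisco_limited(ci, 1.0, kinetics))
    g = np.asarray(rubp_limited(ci, 1.0, kinetics))
    n = len(ci)
    cols = []
    cols.append(np.where(limb_c, f, 0.0))
    cols.append(np.where(limb_c, 0.0, g))
    rhs = a.copy()
    if fix_rd is None:
        cols.append(-np.ones(n))
    else:
        rhs = rhs + fix_rd
    X = np.column_stack(cols)
    use = [limb_c.any(), (~limb_c).any()] + ([True] if fix_rd is None else [])
    use = np.array(use)
    sol = np.full(X.shape[1], np.nan)
    if use.any():
        coef, *_ = np.linalg.lstsq(X[:, use], rhs, rcond=None)
        sol[use] = coef
    vc, jm = sol[0], sol[1]
    rd = sol[2] if fix_rd is None else fix_rd
    return vc, jm, rd


def fit_aci(
    curve: ACiCurve,
    kinetics: KineticConstants = DEFAULT_KINETICS,
    *,
    ci_rubisco_max: float = 300.0,
    ci_rubp_min: float = 600.0,
    max_iter: int = 80,
    allow_off_temperature: bool = False,
) -> FvCBParams:
    """Estimate Vcmax, Jmax and Rd from an A-Ci curve.

    Stage 1 fits (Vcmax, Rd) on Rubisco-limited points (Ci <= ``ci_rubisco_max``),
    stage 2 fits Jmax on RuBP-limited points (Ci >= ``ci_rubp_min``) holding Rd,
    stage 3 refines all three jointly: each point is assigned to the limb the
    current parameters predict as limiting, the conditionally-linear least-squares
    problem is solved exactly, and the loop repeats until the assignment is
    stable. The reported sse is the final joint residual sum of squares.
    """
    if not allow_off_temperature and abs(curve.leaf_temp - 25.0) > 0.5:
        raise ValueError(
            f"curve {curve.sample_id!r} measured at {curve.leaf_temp} degC; "
            "fitting assumes 25 degC (pass allow_off_temperature=True to override)"
        )
    if "too-few-points" in curve.flags:
        raise InsufficientSpanError(
            f"curve {curve.sample_id!r} has {len(curve)} points; >= 6 required"
        )
    missing = []
    if "no-low-ci" in curve.flags:
        missing.append("Rubisco-limited region (Ci <= 300)")
    if "no-high-ci" in curve.flags:
        missing.append("RuBP-limited region (Ci >= 600)")
    if missing:
        raise InsufficientSpanError(
            f"curve {curve.sample_id!r} lacks the " + " and the ".join(missing)
        )

    ci, a = curve.ci, curve.a
    flags: list[str] = []

    # stage 1: Rubisco-limited points, A = Vcmax * f - Rd (linear)
    low = ci <= ci_rubisco_max
    f = np.asarray(rubisco_limited(ci, 1.0, kinetics))
    g = np.asarray(rubp_limited(ci, 1.0, kinetics))
    X1 = np.column_stack([f[low], -np.ones(low.sum())])
    (vc, rd), *_ = np.linalg.lstsq(X1, a[low], rcond=None)
    rd = max(rd, 0.0)
    vc = max(vc, 1e-6)

    # stage 2: RuBP-limited points, Jmax with Rd held
    high = ci >= ci_rubp_min
    jm = float(np.sum(g[high] * (a[high] + rd)) / np.sum(g[high] ** 2))
    jm = max(jm, 1e-6)

    # stage 3: limitation-assignment iteration (joint exact least squares)
    def model_sse(vc_, jm_, rd_):
        pred = np.minimum(vc_ * f, jm_ * g) - rd_
        return float(np.sum((a - pred) ** 2))

    best = (model_sse(vc, jm, rd), vc, jm, rd)
    limb_c = vc * f <= jm * g
    for _ in range(max_iter):
        vc_new, jm_new, rd_new = _limb_lstsq(ci, a, limb_c, kinetics)
        if not np.isfinite(vc_new):
            vc_new = best[1]
        if not np.isfinite(jm_new):
            jm_new = best[2]
        if rd_new < 0:
            vc_new, jm_new, rd_new = _limb_lstsq(ci, a, limb_c, kinetics, fix_rd=0.0)
            vc_new = best[1] if not np.isfinite(vc_new) else vc_new
            jm_new = best[2] if not np.isfinite(jm_new) else jm_new
            if "rd-clipped" not in flags:
                flags.append("rd-clipped")
        vc_new, jm_new = max(vc_new, 1e-6), max(jm_new, 1e-6)
        sse = model_sse(vc_new, jm_new, rd_new)
        if sse < best[0]:
            best = (sse, vc_new, jm_new, rd_new)
        new_limb = vc_new * f <= jm_new * g
        if np.array_equal(new_limb, limb_c):
            break
        limb_c = new_limb
    else:
        if not np.isfinite(best[0]):
            raise FitError(
                f"assignment iteration did not converge for {curve.sample_id!r}",
                best=None,
            )
        flags.append("assignment-cycle")

    sse, vc, jm, rd = best
    limb_c = vc * f <= jm * g
    return FvCBParams(
        vcmax=float(vc),
        jmax=float(jm),
        rd=float(rd),
        transition_ci=transition_ci(vc, jm, kinetics),
        sse=sse,
        n_points_c=int(limb_c.sum()),
        n_points_j=int((~limb_c).sum()),
        flags=flags,
    )


_MANDATORY_COLUMNS = ("sample_id", "ci", "a")


def read_gas_exchange(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> list[ACiCurve]:
    """Read a long-format gas-exchange table into per-sample A-Ci curves.

    The table needs columns sample_id, ci, a; step (ladder position),
    leaf_temp and ppfd are used when present. ``column_map`` renames
    instrument-export columns onto these names, e.g. ``{"Ci": "ci"}``.
    Curves are grouped by sample_id and ordered by step (file order
    otherwise). Short or span-deficient curves are returned flagged, not
    dropped.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for col in ("ci", "a", "step", "leaf_temp", "ppfd"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = ", ".join(str(i + 2) for i in df.index[bad][:5])  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at file row(s) {rows}")
        df[col] = coerced

    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        if "step" in grp.columns:
            grp = grp.sort_values("step", kind="stable")
        kwargs = {}
        if "leaf_temp" in grp.columns:
            kwargs["leaf_temp"] = float(grp["leaf_temp"].iloc[0])
        if "ppfd" in grp.columns:
            kwargs["ppfd"] = float(grp["ppfd"].iloc[0])
        curves.append(
            ACiCurve(
                sample_id=str(sample_id),
                ci=grp["ci"].to_numpy(),
                a=grp["a"].to_numpy(),
                **kwargs,
            )
        )
    return curves


def params_table(fits: dict[str, FvCBParams]) -> pd.DataFrame:
    """One row per sample of fitted parameters, for params.csv."""
    rows = []
    for sample_id, p in fits.items():
        rows.append(
            {
                "sample_id": sample_id,
                "vcmax": p.vcmax,
                "jmax": p.jmax,
                "rd": p.rd,
                "transition_ci": p.transition_ci,
                "sse": p.sse,
                "n_points_c": p.n_points_c,
                "n_points_j": p.n_points_j,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows)
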