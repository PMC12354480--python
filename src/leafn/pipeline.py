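"""End-to-end orchestration: simulate/load -> fit -> quantify -> partition -> analyze.

``run_pipeline`` takes a :class:`PipelineConfig` (from YAML or built in
Python), runs the stages in dependency order and writes all artifacts plus a
run manifest into the output directory. A failure in one sample is logged
and drops that sample (strict mode aborts instead). All randomness flows
from one root seed, split per stage.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fvcb import (FitError, InsufficientSpanError, KineticConstants,
                   fit_aci, params_table, read_gas_exchange)
from .importance import ImportanceConfig, importance_report, rf_importance
from .metrics import anova_table, pnue, pool_regressions, regressions_to_frame
from .partition import POOLS, LeafSample, PartitionConstants, group_means, partition_table
from .pigments import pigment_table, read_absorbances
from .synthetic import DesignConfig, TruthProfile, generate_experiment

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationReport", "run_pipeline", "validate_inputs"]

ANOVA_RESPONSES = ("na", "asat", "pnue", "vcmax", "jmax", "chla_mg_g", "chlb_mg_g", "chlt_mg_g")
IMPORTANCE_FEATURES = (
    "na", "n_resp", "n_cb", "n_et", "n_cl", "n_str", "n_store",
    "frac_resp", "frac_cb", "frac_et", "frac_cl", "frac_str", "frac_store",
)


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (paths or a simulate block), knobs, output."""

    outdir: str = "leafn_run"
    seed: int = 0
    simulate: bool = True
    traits_path: str | None = None
    aci_path: str | None = None
    absorbance_path: str | None = None
    constants: dict = field(default_factory=dict)  # PartitionConstants overrides
    kinetics: dict = field(default_factory=dict)  # KineticConstants overrides
    n_trees: int = 500
    n_null_permutations: int = 100
    strict: bool = False
    exclude_negative_storage: bool = True  # from regressions/importance, not tables
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = (self.traits_path, self.aci_path, self.absorbance_path)
        if not self.simulate and not all(paths):
            raise ValueError(
                "config must either set simulate=true or provide traits/aci/absorbance paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {"ok": self.ok, "issues": self.issues, "warnings": self.warnings}


def validate_inputs(traits_path, aci_path, absorbance_path) -> ValidationReport:
    """Schema and cross-table checks; report-only, never raises on bad data."""
    rep = ValidationReport()

    def load(path, name, required):
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file is an issue, not a crash
            rep.issues.append(f"{name}: unreadable ({exc})")
            return None
        missing = [c for c in required if c not in df.columns]
        if missing:
            rep.issues.append(f"{name}: missing column(s) {', '.join(missing)}")
            return None
        return df

    traits = load(traits_path, "traits", ("sample_id", "na", "n_str", "lma", "asat"))
    aci = load(aci_path, "aci_curves", ("sample_id", "ci", "a"))
    absorb = load(absorbance_path, "absorbance", ("sample_id", "a665", "a649"))
    if traits is None or aci is None or absorb is None:
        return rep

    if (traits["na"] <= 0).any():
        bad = traits.loc[traits["na"] <= 0, "sample_id"].tolist()
        rep.issues.append(f"traits: non-positive na for {bad}")
    outside = traits[(traits["na"] < 0.5) | (traits["na"] > 6.0)]
    for sid, na in zip(outside["sample_id"], outside["na"]):
        rep.warnings.append(f"traits: {sid} na={na:.3g} outside typical 0.5-6 g m-2")

    tset = set(traits["sample_id"].astype(str))
    for name, df in (("aci_curves", aci), ("absorbance", absorb)):
        other = set(df["sample_id"].astype(str))
        for sid in sorted(tset - other):
            rep.issues.append(f"{name}: sample {sid} missing (downstream values will be dropped)")
        for sid in sorted(other - tset):
            rep.warnings.append(f"{name}: orphan sample {sid} not in traits")

    counts = aci.groupby("sample_id").size()
    for sid in counts.index[counts < 6]:
        rep.warnings.append(f"aci_curves: sample {sid} has {counts[sid]} points (<6, unfittable)")
    return rep


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write artifacts under ``config.outdir``. Returns the path."""
    logging.basicConfig(level=config.log_level, stream=sys.stderr, force=False)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    constants = PartitionConstants(**config.constants)
    kinetics = KineticConstants(**config.kinetics)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "constants": asdict(constants),
        "kinetics": asdict(kinetics),
        "stages": {},
    }

    # stage 0: inputs. The simulated "world" always uses the package-default
    # constants and kinetics; config overrides apply to the analysis stages,
    # so overriding e.g. cb is a sensitivity analysis, not a change of truth.
    if config.simulate:
        design = DesignConfig(seed=_stage_seed(config.seed, 0))
        truth = TruthProfile.default(design)
        dataset = generate_experiment(design, truth)
        input_dir = out / "inputs"
        paths = dataset.write(input_dir)
        traits_path, aci_path, absorbance_path = (
            paths["traits"], paths["aci_curves"], paths["absorbance"]
        )
        manifest["inputs"] = {k: str(v) for k, v in paths.items()}
    else:
        traits_path, aci_path, absorbance_path = (
            config.traits_path, config.aci_path, config.absorbance_path
        )
        manifest["inputs"] = {
            "traits": str(traits_path), "aci_curves": str(aci_path),
            "absorbance": str(absorbance_path),
        }

    traits = pd.read_csv(traits_path)
    manifest["stages"]["traits"] = {"rows": len(traits)}

    # stage 1: A-Ci fits
    curves = read_gas_exchange(aci_path)
    fits = {}
    for curve in curves:
        try:
            fits[curve.sample_id] = fit_aci(curve, kinetics)
        except (InsufficientSpanError, FitError, ValueError) as exc:
            log.error("fit_aci failed for %s: %s", curve.sample_id, exc)
            if config.strict:
                raise
    params = params_table(fits)
    params.to_csv(out / "params.csv", index=False)
    manifest["stages"]["fit_aci"] = {"curves": len(curves), "fitted": len(fits)}

    # stage 2: pigments
    records = read_absorbances(absorbance_path)
    lma_map = dict(zip(traits["sample_id"].astype(str), traits["lma"]))
    pigments = pigment_table(records, lma_by_sample=lma_map)
    pigments.to_csv(out / "pigments.csv", index=False)
    manifest["stages"]["pigments"] = {"rows": len(pigments)}

    # stage 3: merge + partition
    merged = traits.merge(params, on="sample_id", how="inner", suffixes=("", "_fit"))
    merged = merged.merge(
        pigments[["sample_id", "chla_mg_g", "chlb_mg_g", "chlt_mg_g", "cc_mmol_m2"]],
        on="sample_id", how="inner",
    )
    samples = []
    for _, row in merged.iterrows():
        try:
            samples.append(
                LeafSample(
                    sample_id=str(row["sample_id"]),
                    na=row["na"], vcmax=row["vcmax"], jmax=row["jmax"],
                    cc=row["cc_mmol_m2"], n_str=row["n_str"],
                    cultivar=str(row.get("cultivar", "")),
                    n_level=str(row.get("n_level", "")),
                    replicate=str(row.get("replicate", "")),
                    asat=row["asat"], gsw=row.get("gsw", float("nan")),
                    lma=row["lma"], rd=row["rd"],
                )
            )
        except ValueError as exc:
            log.error("partition input invalid: %s", exc)
            if config.strict:
                raise
    pools_long, fracs_long = partition_table(samples, constants)
    pools_long.to_csv(out / "pools.csv", index=False)
    fracs_long.to_csv(out / "fractions.csv", index=False)
    group_means(pools_long).to_csv(out / "pool_group_means.csv", index=False)
    (out / "constants.json").write_text(constants.to_json())
    manifest["stages"]["partition"] = {
        "samples": len(samples),
        "negative_storage": int((pools_long["flags"] == "negative-storage").sum() // len(POOLS)),
    }

    # stage 4: wide analysis table (pools as columns, fractions, PNUE)
    wide = pools_long.pivot(index="sample_id", columns="pool", values="value").reset_index()
    wide = wide.merge(
        fracs_long.pivot(index="sample_id", columns="pool", values="fraction")
        .rename(columns=lambda c: "frac_" + c.removeprefix("n_"))
        .reset_index(),
        on="sample_id",
    )
    wide = wide.merge(merged, on="sample_id", suffixes=("", "_in"))
    wide["pnue"] = pnue(wide["asat"], wide["na"])
    wide["n_nonpsn"] = wide["n_resp"] + wide["n_str"] + wide["n_store"]
    flagged = {p.sample_id for p in samples} - set(
        pools_long.loc[pools_long["flags"] == "", "sample_id"]
    )
    analysis = wide[~wide["sample_id"].isin(flagged)] if config.exclude_negative_storage else wide
    wide.to_csv(out / "analysis_table.csv", index=False)

    # stage 5: regressions + ANOVA
    regs = pool_regressions(analysis, "asat", response_label="Pn") + pool_regressions(
        analysis, "pnue", response_label="PNUE"
    )
    regressions_to_frame(regs).to_csv(out / "regressions.csv", index=False)
    responses = [c for c in ANOVA_RESPONSES if c in wide.columns]
    anova_table(wide, responses).to_csv(out / "anova.csv", index=False)
    manifest["stages"]["metrics"] = {"regressions": len(regs), "anova_responses": responses}

    # stage 6: importance
    results = {}
    summary = {}
    for label, col, stage in (("Pn", "asat", 1), ("PNUE", "pnue", 2)):
        cfg = ImportanceConfig(
            n_trees=config.n_trees,
            n_null_permutations=config.n_null_permutations,
            seed=_stage_seed(config.seed, stage),
            response=col,
            features=tuple(f for f in IMPORTANCE_FEATURES if f in analysis.columns),
        )
        res = rf_importance(analysis, cfg)
        results[label] = res
        res.as_frame().to_csv(out / f"importance_{label.lower()}.csv", index=False)
        summary[label] = {
            "explained_variance_pct": res.explained_variance_pct,
            "model_p_value": res.model_p_value,
            "n": res.n,
        }
    importance_report(results).to_csv(out / "importance_report.csv", index=False)
    (out / "importance_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["stages"]["importance"] = summary

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
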