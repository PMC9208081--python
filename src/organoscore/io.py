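"""File formats, configuration and end-to-end pipeline orchestration.

All tabular schemas are plain CSV (UTF-8, decimal point); readers validate
required headers and dtypes with row-level error messages and pass unknown
columns through untouched.  ``run_pipeline`` chains simulate (optional) ->
fit -> score -> associate -> screen/concordance (optional) and writes a JSON
run manifest with the seed, package version and a SHA-256 hash of every
output, so a rerun under the same configuration is byte-checkable.

Doses are stored in µM by default; drugs assayed in other units (e.g. an
antibody in µg/mL) are handled as opaque units — the AUC and score operate
on the log10 span of the dose grid regardless of unit, so no conversion is
required unless curves in different units must be overlaid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_response import DoseResponseTransformer
from .scoring import DEFAULT_THRESHOLD, build_profiles
from .simulate import SimulationConfig, simulate_cohort, simulate_screen_pair, write_cohort
from .stats import associate_cohort

__all__ = [
    "read_viability",
    "read_clinical",
    "read_genotype",
    "read_curves",
    "read_profiles",
    "PipelineConfig",
    "run_pipeline",
    "fit_stage",
    "score_stage",
    "associate_stage",
]

VIABILITY_REQUIRED = ("organoid", "drug", "concentration_um", "replicate", "signal")
CLINICAL_REQUIRED = ("patient", "regimen")
GENOTYPE_REQUIRED = ("organoid", "anti_egfr_resistant", "rnf43_lof")
CURVES_REQUIRED = ("organoid", "drug", "auc_span")
PROFILES_REQUIRED = ("organoid", "organoid_score", "risk_class")


class SchemaError(ValueError):
    """A file violated its schema (missing column or bad value)."""


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[coerced.isna() & df[col].notna()]
    if len(bad):
        raise SchemaError(f"{what}: non-numeric value in column {col!r} at row "
                          f"{int(bad[0])}")
    return coerced


_BOOL_MAP = {"True": True, "False": False, "true": True, "false": False,
             True: True, False: False, 1: True, 0: False, "1": True, "0": False}


def _to_bool(s: pd.Series, what: str) -> pd.Series:
    out = s.map(_BOOL_MAP)
    if out.isna().any():
        row = int(s.index[out.isna()][0])
        raise SchemaError(f"{what}: non-boolean value in column {s.name!r} at row {row}")
    return out.astype(bool)


def read_viability(path: str | Path) -> pd.DataFrame:
    """Long-format viability table; validates dtypes, keeps extra columns."""
    df = pd.read_csv(path)
    _check_columns(df, VIABILITY_REQUIRED, "viability table")
    df["concentration_um"] = _check_numeric(df, "concentration_um", "viability table")
    df["signal"] = _check_numeric(df, "signal", "viability table")
    neg = df.index[df["concentration_um"] < 0]
    if len(neg):
        raise SchemaError(f"viability table: negative concentration at row {int(neg[0])}")
    if "is_vehicle" in df.columns:
        df["is_vehicle"] = df["is_vehicle"].astype(bool)
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    # "N/A" is a legitimate best-response label, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _check_columns(df, CLINICAL_REQUIRED, "clinical table")
    for col in ("size_change_pct", "pfs_days"):
        if col in df.columns:
            df[col] = _check_numeric(df, col, "clinical table")
    for col in df.columns:
        if col == "event" or col.startswith("exclude_") or col == "progression":
            df[col] = _to_bool(df[col], "clinical table")
    return df


def read_genotype(path: str | Path) -> pd.DataFrame:
    # keep empty evidence strings as "", not NaN
    df = pd.read_csv(path, keep_default_na=False)
    _check_columns(df, GENOTYPE_REQUIRED, "genotype table")
    for col in ("anti_egfr_resistant", "rnf43_lof", "apc_truncating"):
        if col in df.columns:
            df[col] = _to_bool(df[col], "genotype table")
    return df


def read_curves(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CURVES_REQUIRED, "curves table")
    df["auc_span"] = _check_numeric(df, "auc_span", "curves table")
    return df


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PROFILES_REQUIRED, "profiles table")
    df["organoid_score"] = _check_numeric(df, "organoid_score", "profiles table")
    df["risk_class"] = df["risk_class"].fillna("")
    return df


def read_cohort(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Load the file set written by :func:`organoscore.simulate.write_cohort`."""
    directory = Path(directory)
    return {
        "viability": read_viability(directory / "viability.csv"),
        "clinical": read_clinical(directory / "clinical.csv"),
        "genotype": read_genotype(directory / "genotype.csv"),
        "ground_truth": pd.read_csv(directory / "ground_truth.csv"),
    }


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-loadable)."""

    out_dir: str = "organoscore_run"
    seed: int = 0
    threshold: float = DEFAULT_THRESHOLD
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)
    simulate: bool = True
    fit_ic50: bool = True
    run_screen: bool = False
    viability_path: str | None = None  # required when simulate is False
    clinical_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fit_stage(viability: pd.DataFrame, *, fit_ic50: bool = True) -> pd.DataFrame:
    """Viability table -> curves table with auc_raw/span/norm (and 4PL fit)."""
    tr = DoseResponseTransformer(fit_ic50=fit_ic50).fit(viability)
    return tr.transform(viability)


def score_stage(curves: pd.DataFrame, clinical: pd.DataFrame,
                threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Curves table -> profiles table (drug scores, organoid score, risk)."""
    col = "auc_norm" if "auc_norm" in curves.columns else "auc_span"
    wide = curves.pivot(index="organoid", columns="drug", values=col)
    if col == "auc_span":
        wide = wide / wide.max(axis=0)
    return build_profiles(wide, clinical, threshold=threshold)


def associate_stage(profiles: pd.DataFrame, clinical: pd.DataFrame):
    return associate_cohort(profiles, clinical)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Identical config and seed give identical output files and manifest
    hashes.  Any stage failure raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            outputs.update(write_cohort(cohort, out))
            viability, clinical = cohort.viability, cohort.clinical
        else:
            if not config.viability_path:
                raise SchemaError("viability_path is required when simulate is off")
            viability = read_viability(config.viability_path)
            if not config.clinical_path:
                raise SchemaError("clinical_path is required for the associate stage")
            clinical = read_clinical(config.clinical_path)

        stage = "fit"
        curves = fit_stage(viability, fit_ic50=config.fit_ic50)
        outputs["curves"] = out / "curves.csv"
        curves.to_csv(outputs["curves"], index=False)

        stage = "score"
        profiles = score_stage(curves, clinical, threshold=config.threshold)
        outputs["profiles"] = out / "profiles.csv"
        profiles.to_csv(outputs["profiles"], index=False)

        stage = "associate"
        report = associate_stage(profiles, clinical)
        outputs["association"] = out / "association.json"
        outputs["association"].write_text(json.dumps(report.to_dict(), indent=2))
        for name, km in report.km_tables.items():
            p = out / f"km_{name}.csv"
            outputs[f"km_{name}"] = p
            km.to_csv(p, index=False)

        if config.run_screen:
            stage = "screen"
            from .repurposing import auc_zscore, replicate_concordance

            pair = simulate_screen_pair(seed=config.seed)
            _, median_r = replicate_concordance(pair.rep1, pair.rep2)
            z, flagged = auc_zscore((pair.rep1 + pair.rep2) / 2)
            outputs["screen_z"] = out / "screen_z.csv"
            z.to_csv(outputs["screen_z"])
            outputs["screen_summary"] = out / "screen_summary.json"
            outputs["screen_summary"].write_text(json.dumps(
                {"median_replicate_pearson_r": median_r,
                 "zero_variance_drugs": flagged}, indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "sha256": {k: _sha256(v) for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
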