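"""Synthetic organoid-cohort generator.

Emulates a patient-derived organoid (PDO) drug screen with the statistical
structure the downstream analysis assumes: per-organoid latent drug
resistance, 6-point 10-fold dilution viability curves with replicate noise,
genotype flags coupled to specific drug sensitivities, and clinical outcomes
(RECIST-like tumor-size change, censored progression-free survival) linked to
the latent resistance of the drugs in each patient's regimen.

The generative model
--------------------
For organoid *o* and drug *d* the latent resistance is

    rho[o, d] = clip(w * u[o] + (1 - w) * v[o, d] + genotype shifts, 0, 1)

with ``u`` an organoid-level factor and ``v`` drug-specific variation, both
Beta-distributed; ``w`` is the organoid mixing weight.  Resistance maps
linearly onto the assay scale, ``log10 IC50[o, d] = lo_d + rho * (hi_d - lo_d)``,
and true viability at concentration *c* follows a four-parameter logistic with
top 1, bottom 0.1 and Hill slope 1.  Observed replicate signals are the true
viability times a per-organoid plate scale times multiplicative Gaussian noise
(floored at zero); vehicle wells are scale * noise.

Clinical outcomes: tumor-size change is a linear function of the mean rho over
the drugs in the assigned regimen plus Gaussian noise; progression-free
survival is exponential proportional-hazards on the latent score
``1 + 3 * mean(rho)`` (the organoid-score scale) with uniform censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import map_regimen

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "ScreenPair",
    "simulate_cohort",
    "simulate_screen_pair",
    "write_cohort",
    "default_screen_config",
]

# log10 IC50 ranges (in log10 µM) spanning sensitive -> resistant organoids
DEFAULT_DRUGS: dict[str, tuple[float, float]] = {
    "5-FU": (-1.0, 1.0),
    "oxaliplatin": (0.0, 1.7),
    "SN38": (-3.0, -1.0),
    "cetuximab": (-1.0, 2.0),
}

_REGIMENS_NO_CETUX = (
    "FOLFOX",
    "FOLFIRI",
    "FOLFOX + Bevacizumab",
    "FOLFIRI + Bevacizumab",
)
_REGIMENS_CETUX = ("FOLFOX + Cetuximab", "FOLFIRI + Cetuximab")

BSC_REGIMEN = "Best supportive care"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    Dose geometry follows the screening protocol (6-point, 10-fold serial
    dilution from 10 µM, three replicates); effect sizes are the defaults of
    the generative model described in the module docstring.
    """

    n_organoids: int = 54
    drugs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DRUGS)
    )
    n_replicates: int = 3
    dose_top: float = 10.0
    n_doses: int = 6
    dilution_factor: float = 10.0
    noise_cv: float = 0.10
    n_vehicle_wells: int = 2
    # latent-resistance construction
    organoid_weight: float = 0.7
    beta_a: float = 1.5
    beta_b: float = 1.5
    class_weight: float = 0.5
    target_classes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    # dose-response shape
    resp_top: float = 1.0
    resp_bottom: float = 0.1
    resp_hill: float = 1.0
    # clinical linkage
    regression_intercept: float = -60.0
    regression_slope: float = 80.0
    regression_sd: float = 10.0
    baseline_hazard: float = 6.0e-4
    score_log_hr: float = math.log(2.0)
    censor_window: tuple[float, float] = (200.0, 800.0)
    # genotype coupling
    hotspot_prob: float = 0.4
    hotspot_shift: float = 0.4
    rnf43_prob: float = 0.1
    rnf43_shift: float = -0.4
    porcn_drug: str = "LGK974"
    # cohort composition (analysis-exclusion flags)
    n_bsc: int = 10
    n_low_concordance: int = 2
    n_post_treatment: int = 1
    n_lost_followup: int = 1
    n_palliative: int = 13
    seed: int = 0

    def validate(self) -> None:
        if self.n_organoids <= 0:
            raise ValueError("n_organoids must be positive")
        if not self.drugs:
            raise ValueError("drug list must not be empty")
        if self.n_doses < 2:
            raise ValueError("n_doses must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for p in (self.hotspot_prob, self.rnf43_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.organoid_weight <= 1.0:
            raise ValueError("organoid_weight must lie in [0, 1]")
        if not 0.0 <= self.class_weight <= 1.0:
            raise ValueError("class_weight must lie in [0, 1]")
        for name, (lo, hi) in self.drugs.items():
            if not lo <= hi:
                raise ValueError(f"log10-IC50 range for {name!r} is not well ordered")
        lo, hi = self.censor_window
        if not 0 < lo <= hi:
            raise ValueError("censor_window must be well ordered and positive")
        n_excl = (
            self.n_bsc
            + self.n_low_concordance
            + self.n_post_treatment
            + self.n_lost_followup
        )
        if n_excl > self.n_organoids:
            raise ValueError("exclusion counts exceed cohort size")

    def dose_grid(self) -> np.ndarray:
        """Descending geometric dose series (µM)."""
        return self.dose_top / self.dilution_factor ** np.arange(self.n_doses)


@dataclass
class SimulatedCohort:
    """Observables plus ground truth of one simulated cohort."""

    viability: pd.DataFrame
    clinical: pd.DataFrame
    genotype: pd.DataFrame
    rho: pd.DataFrame  # organoid x drug latent resistance in [0, 1]
    ic50: pd.DataFrame  # organoid x drug log10 IC50 (µM)
    config: SimulationConfig


@dataclass
class ScreenPair:
    """Two independent replicate screens of the same organoids and library."""

    rep1: pd.DataFrame  # organoid x drug auc_span
    rep2: pd.DataFrame
    rho: pd.DataFrame
    genotype: pd.DataFrame
    target_classes: dict[str, tuple[str, ...]]


def _four_pl(conc: np.ndarray, top: float, bottom: float, hill: float,
             ic50: np.ndarray) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def _draw_genotype(cfg: SimulationConfig, rng: np.random.Generator,
                   organoids: list[str]) -> pd.DataFrame:
    hotspot = rng.random(len(organoids)) < cfg.hotspot_prob
    rnf43 = rng.random(len(organoids)) < cfg.rnf43_prob
    evidence = []
    for h, r in zip(hotspot, rnf43):
        ev = []
        if h:
            ev.append("KRAS G12D missense VAF=0.45")
        if r:
            ev.append("RNF43 c.1595delG frameshift VAF=0.90")
        evidence.append("; ".join(ev))
    return pd.DataFrame(
        {
            "organoid": organoids,
            "anti_egfr_resistant": hotspot,
            "rnf43_lof": rnf43,
            "evidence": evidence,
        }
    )


def _draw_rho(cfg: SimulationConfig, rng: np.random.Generator,
              organoids: list[str], genotype: pd.DataFrame) -> pd.DataFrame:
    drugs = list(cfg.drugs)
    n, m = len(organoids), len(drugs)
    u = rng.beta(cfg.beta_a, cfg.beta_b, size=n)
    classes = {d: c for c, members in cfg.target_classes.items() for d in members}
    class_names = sorted(set(classes.values()))
    class_factor = rng.beta(cfg.beta_a, cfg.beta_b, size=(n, max(len(class_names), 1)))
    v = rng.beta(cfg.beta_a, cfg.beta_b, size=(n, m))
    for j, d in enumerate(drugs):
        if d in classes:
            k = class_names.index(classes[d])
            v[:, j] = (1 - cfg.class_weight) * v[:, j] + cfg.class_weight * class_factor[:, k]
    rho = cfg.organoid_weight * u[:, None] + (1 - cfg.organoid_weight) * v
    hotspot = genotype["anti_egfr_resistant"].to_numpy()
    rnf43 = genotype["rnf43_lof"].to_numpy()
    if "cetuximab" in drugs:
        rho[:, drugs.index("cetuximab")] += np.where(hotspot, cfg.hotspot_shift, 0.0)
    if cfg.porcn_drug in drugs:
        rho[:, drugs.index(cfg.porcn_drug)] += np.where(rnf43, cfg.rnf43_shift, 0.0)
    rho = np.clip(rho, 0.0, 1.0)
    return pd.DataFrame(rho, index=organoids, columns=drugs)


def _viability_table(cfg: SimulationConfig, rng: np.random.Generator,
                     rho: pd.DataFrame, scales: np.ndarray) -> pd.DataFrame:
    organoids = list(rho.index)
    drugs = list(rho.columns)
    lo = np.array([cfg.drugs[d][0] for d in drugs])
    hi = np.array([cfg.drugs[d][1] for d in drugs])
    log_ic50 = lo[None, :] + rho.to_numpy() * (hi - lo)[None, :]
    ic50 = 10.0 ** log_ic50  # (n, m)
    doses = cfg.dose_grid()  # (k,)
    true_v = _four_pl(
        doses[None, None, :], cfg.resp_top, cfg.resp_bottom, cfg.resp_hill,
        ic50[:, :, None],
    )  # (n, m, k)
    n, m, k, r = len(organoids), len(drugs), cfg.n_doses, cfg.n_replicates
    noise = rng.normal(0.0, cfg.noise_cv, size=(n, m, k, r)) if cfg.noise_cv > 0 else np.zeros((n, m, k, r))
    signal = np.maximum(true_v[:, :, :, None] * (1.0 + noise), 0.0)
    signal = signal * scales[:, None, None, None]

    nv = cfg.n_vehicle_wells
    vnoise = rng.normal(0.0, cfg.noise_cv, size=(n, m, nv, r)) if cfg.noise_cv > 0 else np.zeros((n, m, nv, r))
    vsignal = np.maximum(1.0 + vnoise, 0.0) * scales[:, None, None, None]

    org_idx = np.repeat(np.arange(n), m * k * r)
    drug_idx = np.tile(np.repeat(np.arange(m), k * r), n)
    dose_idx = np.tile(np.repeat(np.arange(k), r), n * m)
    rep_idx = np.tile(np.arange(r), n * m * k)
    dose_rows = pd.DataFrame(
        {
            "organoid": np.array(organoids)[org_idx],
            "drug": np.array(drugs)[drug_idx],
            "concentration_um": doses[dose_idx],
            "replicate": rep_idx + 1,
            "signal": signal.reshape(-1),
            "is_vehicle": False,
        }
    )
    vorg = np.repeat(np.arange(n), m * nv * r)
    vdrug = np.tile(np.repeat(np.arange(m), nv * r), n)
    vwell = np.tile(np.repeat(np.arange(nv), r), n * m)
    vrep = np.tile(np.arange(r), n * m * nv)
    veh_rows = pd.DataFrame(
        {
            "organoid": np.array(organoids)[vorg],
            "drug": np.array(drugs)[vdrug],
            "concentration_um": 0.0,
            "replicate": vrep + 1,
            "signal": vsignal.reshape(-1),
            "is_vehicle": True,
        }
    )
    # unused vwell index only orders the vehicle wells deterministically
    del vwell
    table = pd.concat([dose_rows, veh_rows], ignore_index=True)
    table["plate"] = table["organoid"]
    return table.sort_values(
        ["organoid", "drug", "is_vehicle", "concentration_um", "replicate"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def _assign_clinical(cfg: SimulationConfig, rng: np.random.Generator,
                     organoids: list[str], rho: pd.DataFrame,
                     genotype: pd.DataFrame) -> pd.DataFrame:
    n = len(organoids)
    order = rng.permutation(n)
    status = np.array(["evaluable"] * n, dtype=object)
    pos = 0
    for label, count in (
        ("bsc", cfg.n_bsc),
        ("low_concordance", cfg.n_low_concordance),
        ("post_treatment", cfg.n_post_treatment),
        ("lost_followup", cfg.n_lost_followup),
    ):
        status[order[pos:pos + count]] = label
        pos += count
    evaluable_idx = [i for i in range(n) if status[i] == "evaluable"]
    pall_pick = rng.permutation(len(evaluable_idx))[: min(cfg.n_palliative, len(evaluable_idx))]
    palliative = set(np.array(evaluable_idx)[pall_pick].tolist())

    hotspot = genotype["anti_egfr_resistant"].to_numpy()
    screened = set(rho.columns)
    rows = []
    regimen_draw = rng.random(n)
    size_noise = rng.normal(0.0, cfg.regression_sd, size=n)
    pfs_draw = rng.random(n)
    censor = rng.uniform(*cfg.censor_window, size=n)
    for i, org in enumerate(organoids):
        st = status[i]
        if st == "bsc":
            rows.append(
                dict(patient=org, regimen=BSC_REGIMEN, setting="none",
                     size_change_pct=np.nan, pfs_days=np.nan, event=False,
                     best_response="N/A", exclude_bsc=True,
                     exclude_low_concordance=False, exclude_post_treatment=False,
                     exclude_lost_followup=False, progression=False)
            )
            continue
        pool = _REGIMENS_NO_CETUX if hotspot[i] else _REGIMENS_NO_CETUX + _REGIMENS_CETUX
        regimen = pool[int(regimen_draw[i] * len(pool))]
        components = map_regimen(regimen, screened).components
        mean_rho = float(rho.loc[org, list(components)].mean()) if components else np.nan
        latent_score = 1.0 + 3.0 * mean_rho
        in_pall = i in palliative
        size_change = (
            cfg.regression_intercept + cfg.regression_slope * mean_rho + size_noise[i]
            if in_pall
            else np.nan
        )
        hazard = cfg.baseline_hazard * math.exp(cfg.score_log_hr * latent_score)
        t_event = -math.log(pfs_draw[i]) / hazard
        t_obs = min(t_event, censor[i])
        event = t_event <= censor[i]
        if np.isnan(size_change):
            best = "N/A"
        elif size_change <= -30:
            best = "PR"
        elif size_change >= 20:
            best = "PD"
        else:
            best = "SD"
        rows.append(
            dict(patient=org, regimen=regimen,
                 setting="palliative" if in_pall else "adjuvant",
                 size_change_pct=size_change, pfs_days=t_obs, event=event,
                 best_response=best, exclude_bsc=False,
                 exclude_low_concordance=st == "low_concordance",
                 exclude_post_treatment=st == "post_treatment",
                 exclude_lost_followup=st == "lost_followup",
                 progression=event)
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig | None = None, *,
                    seed: int | None = None) -> SimulatedCohort:
    """Draw one synthetic cohort under the generative model.

    ``seed`` overrides ``config.seed``; a fixed seed gives bit-identical
    output.  Random draws happen in a fixed order (genotype, latent factors,
    viability noise, regimen assignment, outcomes) so the cohort is stable
    under the same configuration.
    """
    cfg = config if config is not None else SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    organoids = [f"ORG-{i + 1:03d}" for i in range(cfg.n_organoids)]

    genotype = _draw_genotype(cfg, rng, organoids)
    rho = _draw_rho(cfg, rng, organoids, genotype)
    scales = 1.0e5 * rng.uniform(0.5, 2.0, size=cfg.n_organoids)
    viability = _viability_table(cfg, rng, rho, scales)
    clinical = _assign_clinical(cfg, rng, organoids, rho, genotype)

    drugs = list(cfg.drugs)
    lo = np.array([cfg.drugs[d][0] for d in drugs])
    hi = np.array([cfg.drugs[d][1] for d in drugs])
    ic50 = pd.DataFrame(
        lo[None, :] + rho.to_numpy() * (hi - lo)[None, :],
        index=organoids, columns=drugs,
    )
    return SimulatedCohort(viability=viability, clinical=clinical,
                           genotype=genotype, rho=rho, ic50=ic50, config=cfg)


def default_screen_config(n_organoids: int = 10, *, noise_cv: float = 0.05,
                          seed: int = 0) -> SimulationConfig:
    """Configuration emulating the FDA-library repurposing screen.

    A compact oncology library with drug classes sharing targets (CDK4/6,
    PARP, EGFR/HER2), the porcupine inhibitor LGK974, and assorted singletons;
    screened on a small refractory sub-cohort at lower assay noise.  Drugs
    sharing a target are driven mostly by one latent class factor
    (class_weight 0.8), mirroring the near-duplicate within-class response
    patterns such screens show; about one refractory organoid in five
    carries an RNF43 loss-of-function genotype.
    """
    library: dict[str, tuple[float, float]] = {
        "ribociclib": (-1.0, 1.0), "palbociclib": (-1.0, 1.0),
        "abemaciclib": (-1.0, 1.0),
        "niraparib": (-0.5, 1.0), "talazoparib": (-1.5, 0.5),
        "rucaparib": (-0.5, 1.0), "olaparib": (-0.5, 1.0),
        "gefitinib": (-1.0, 1.0), "erlotinib": (-1.0, 1.0),
        "afatinib": (-1.5, 0.5), "lapatinib": (-1.0, 1.0),
        "LGK974": (-2.5, 1.0),
        "paclitaxel": (-2.0, 0.0), "doxorubicin": (-1.5, 0.5),
        "sunitinib": (-1.0, 1.0), "vorinostat": (-0.5, 1.0),
    }
    classes = {
        "CDK4/6": ("ribociclib", "palbociclib", "abemaciclib"),
        "PARP": ("niraparib", "talazoparib", "rucaparib", "olaparib"),
        "EGFR/HER2": ("gefitinib", "erlotinib", "afatinib", "lapatinib"),
    }
    return SimulationConfig(
        n_organoids=n_organoids, drugs=library, noise_cv=noise_cv,
        target_classes=classes, class_weight=0.8, rnf43_prob=0.2, seed=seed,
        n_bsc=0, n_low_concordance=0, n_post_treatment=0, n_lost_followup=0,
        n_palliative=0,
    )


def simulate_screen_pair(config: SimulationConfig | None = None, *,
                         seed: int | None = None) -> ScreenPair:
    """Two independent replicate screens sharing one latent-resistance draw.

    Returns per-replicate organoid x drug ``auc_span`` matrices computed
    through the dose-response pipeline, so replicate disagreement reflects
    only assay noise.
    """
    from .dose_response import summarize_cohort

    cfg = config if config is not None else default_screen_config()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    organoids = [f"ORG-{i + 1:03d}" for i in range(cfg.n_organoids)]
    genotype = _draw_genotype(cfg, rng, organoids)
    rho = _draw_rho(cfg, rng, organoids, genotype)
    scales = 1.0e5 * rng.uniform(0.5, 2.0, size=cfg.n_organoids)
    mats = []
    for _ in range(2):
        table = _viability_table(cfg, rng, rho, scales)
        curves = summarize_cohort(table, fit_ic50=False)
        mats.append(curves.pivot(index="organoid", columns="drug",
                                 values="auc_span"))
    classes = {c: tuple(m) for c, m in cfg.target_classes.items()}
    return ScreenPair(rep1=mats[0], rep2=mats[1], rho=rho, genotype=genotype,
                      target_classes=classes)


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write viability, clinical, genotype and ground-truth CSVs.

    Round-trips losslessly through :mod:`organoscore.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = (
        cohort.rho.rename_axis("organoid")
        .reset_index()
        .melt(id_vars="organoid", var_name="drug", value_name="rho")
        .merge(
            cohort.ic50.rename_axis("organoid")
            .reset_index()
            .melt(id_vars="organoid", var_name="drug", value_name="log10_ic50"),
            on=["organoid", "drug"],
        )
    )
    paths = {
        "viability": directory / "viability.csv",
        "clinical": directory / "clinical.csv",
        "genotype": directory / "genotype.csv",
        "ground_truth": directory / "ground_truth.csv",
    }
    cohort.viability.to_csv(paths["viability"], index=False)
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.genotype.to_csv(paths["genotype"], index=False)
    truth.to_csv(paths["ground_truth"], index=False)
    return paths
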