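"""Dose-response quantification: viability normalization, 4PL fits, AUC.

Raw well signals are normalized to the mean of the vehicle-control wells of
their plate group, giving viability fractions.  Per organoid x drug the module
computes (i) a least-squares four-parameter logistic (4PL) fit on log10 dose,
reporting IC50 with right-censoring at the top tested dose when the fitted
curve never reaches half-maximal viability in range, and (ii) the area under
the measured mean-viability curve versus log10 concentration (trapezoidal,
independent of the fit).  ``auc_span`` divides out the log10 dose span so the
value is unitless in [0, top]; ``auc_norm`` divides by the cohort maximum per
drug — the normalized AUC that the quartile drug scores are built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CurveFit",
    "normalize_viability",
    "fit_curve",
    "compute_auc",
    "compute_auc_from_fit",
    "normalize_auc_cohort",
    "summarize_cohort",
    "DoseResponseTransformer",
]


@dataclass(frozen=True)
class CurveFit:
    """4PL parameters; ``ic50_censored`` marks right-censoring at dose_max."""

    top: float
    bottom: float
    hill: float
    ic50: float
    ic50_censored: bool


def _group_keys(table: pd.DataFrame) -> list[str]:
    return ["organoid", "plate"] if "plate" in table.columns else ["organoid"]


def _vehicle_mask(table: pd.DataFrame) -> pd.Series:
    if "is_vehicle" in table.columns:
        return table["is_vehicle"].astype(bool)
    return table["concentration_um"] == 0


def normalize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``viability_fraction`` column: signal / mean vehicle signal.

    The vehicle mean is taken within each (organoid, plate) group (organoid
    alone when no plate column is present), so a well at the vehicle mean maps
    to exactly 1.0.  Fractions are not clipped.

    Raises
    ------
    ValueError
        If a group has no vehicle wells, or a zero vehicle mean.
    """
    if (table["concentration_um"] < 0).any():
        raise ValueError("concentrations must be non-negative")
    keys = _group_keys(table)
    veh = _vehicle_mask(table)
    veh_mean = table[veh].groupby(keys)["signal"].mean()
    out = table.copy()
    grouped = out.groupby(keys, sort=False)
    fractions = np.empty(len(out), dtype=float)
    for key, idx in grouped.indices.items():
        if key not in veh_mean.index:
            raise ValueError(f"no vehicle-control wells for group {key!r}")
        m = veh_mean.loc[key]
        if m == 0:
            raise ValueError(f"vehicle mean is zero for group {key!r}")
        fractions[idx] = out["signal"].to_numpy()[idx] / m
    out["viability_fraction"] = fractions
    return out


def _four_pl(log_c: np.ndarray, top: float, bottom: float, hill: float,
             log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50)))


def fit_curve(doses: np.ndarray, fractions: np.ndarray) -> CurveFit:
    """Least-squares 4PL fit of viability fractions on log10 dose.

    ``doses`` and ``fractions`` are flat, replicate-level arrays of equal
    length (doses may repeat).  Bounds: top in [0.5, 1.5], bottom in [0, 1],
    hill in [0.1, 10], IC50 in [dose_min/100, dose_max*100].  If the fitted
    curve stays above 0.5 over the tested range, IC50 is reported as
    right-censored at the top dose instead of the extrapolated value.
    """
    doses = np.asarray(doses, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if doses.shape != fractions.shape:
        raise ValueError("doses and fractions must have equal length")
    if not np.all(np.isfinite(fractions)):
        raise ValueError("non-finite viability fractions")
    distinct = np.unique(doses[doses > 0])
    if distinct.size < 4:
        raise ValueError("need at least 4 distinct positive doses")
    keep = doses > 0
    log_c = np.log10(doses[keep])
    y = fractions[keep]
    dose_min, dose_max = distinct[0], distinct[-1]
    lo = [0.5, 0.0, 0.1, np.log10(dose_min / 100)]
    hi = [1.5, 1.0, 10.0, np.log10(dose_max * 100)]
    # start near the data: top/bottom from extremes, IC50 at half-max crossing
    y_top = min(max(float(np.max(y)), 0.5 + 1e-9), 1.5 - 1e-9)
    y_bot = min(max(float(np.min(y)), 1e-9), 1.0 - 1e-9)
    half = (y_top + y_bot) / 2
    guess_idx = int(np.argmin(np.abs(y - half)))
    p0 = [y_top, y_bot, 1.0, float(np.clip(log_c[guess_idx], lo[3], hi[3]))]
    try:
        popt, _ = curve_fit(_four_pl, log_c, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
        top, bottom, hill, log_ic50 = popt
    except RuntimeError:
        top, bottom, hill, log_ic50 = p0  # degenerate data; fall back to guess
    # V decreases with dose, so the in-range minimum sits at the top dose
    fitted_at_max = _four_pl(np.log10(dose_max), top, bottom, hill, log_ic50)
    censored = bool(fitted_at_max > 0.5)
    ic50 = dose_max if censored else 10.0 ** log_ic50
    return CurveFit(float(top), float(bottom), float(hill), float(ic50),
                    censored)


def compute_auc(doses: np.ndarray, mean_fractions: np.ndarray) -> tuple[float, float]:
    """Trapezoidal area of mean viability versus log10 concentration.

    Returns ``(auc_raw, auc_span)`` where ``auc_span = auc_raw / log10 dose
    span``.  Viability is clipped to >= 0 before integration; the measured
    grid, not a fitted curve, is integrated.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.clip(np.asarray(mean_fractions, dtype=float), 0.0, None)
    if doses.size != y.size:
        raise ValueError("doses and fractions must have equal length")
    if np.unique(doses).size < 2:
        raise ValueError("need at least 2 distinct doses for an AUC")
    order = np.argsort(doses)
    log_c = np.log10(doses[order])
    auc_raw = float(np.trapezoid(y[order], log_c))
    span = log_c[-1] - log_c[0]
    return auc_raw, auc_raw / span


def compute_auc_from_fit(fit: CurveFit, dose_min: float, dose_max: float,
                         n_points: int = 513) -> tuple[float, float]:
    """AUC of the fitted 4PL over [dose_min, dose_max] in log10 dose.

    Alternative to :func:`compute_auc` for workflows that integrate the
    fitted curve instead of the measured grid; the measured-grid trapezoid
    remains the default throughout the pipeline.
    """
    if not 0 < dose_min < dose_max:
        raise ValueError("need 0 < dose_min < dose_max")
    log_c = np.linspace(np.log10(dose_min), np.log10(dose_max), n_points)
    y = np.clip(_four_pl(log_c, fit.top, fit.bottom, fit.hill,
                         np.log10(fit.ic50)), 0.0, None)
    auc_raw = float(np.trapezoid(y, log_c))
    return auc_raw, auc_raw / (log_c[-1] - log_c[0])


def normalize_auc_cohort(auc_span: pd.Series) -> pd.Series:
    """Divide per-organoid ``auc_span`` by the cohort maximum for one drug.

    The maximal organoid(s) get exactly 1.0; order is preserved.
    """
    vals = auc_span.astype(float)
    if vals.empty or not np.isfinite(vals).any():
        raise ValueError("need at least one finite auc_span value")
    mx = vals.max()
    if mx <= 0:
        raise ValueError("cohort maximum AUC is zero; no drug effect measurable")
    return vals / mx


def summarize_cohort(table: pd.DataFrame, *, fit_ic50: bool = True) -> pd.DataFrame:
    """Per organoid x drug curve summary from a long viability table.

    Normalizes to vehicle, averages replicates per dose, and computes
    ``auc_raw``/``auc_span`` (and the 4PL fit when ``fit_ic50``).  Returns one
    row per (organoid, drug).
    """
    norm = normalize_viability(table)
    norm = norm[~_vehicle_mask(norm)]
    rows = []
    for (org, drug), grp in norm.groupby(["organoid", "drug"], sort=True):
        means = grp.groupby("concentration_um")["viability_fraction"].mean()
        doses = means.index.to_numpy(dtype=float)
        auc_raw, auc_span = compute_auc(doses, means.to_numpy())
        row: dict = {"organoid": org, "drug": drug, "auc_raw": auc_raw,
                     "auc_span": auc_span}
        if fit_ic50:
            fit = fit_curve(grp["concentration_um"].to_numpy(),
                            grp["viability_fraction"].to_numpy())
            row.update(top=fit.top, bottom=fit.bottom, hill=fit.hill,
                       ic50=fit.ic50, ic50_censored=fit.ic50_censored)
        rows.append(row)
    return pd.DataFrame(rows)


class DoseResponseTransformer(BaseEstimator, TransformerMixin):
    """Viability table -> per-curve summary with cohort-normalized AUC.

    ``fit`` learns the per-drug cohort maximum ``auc_span`` (``max_auc_``);
    ``transform`` summarizes a viability table and divides each curve's
    ``auc_span`` by the fitted maximum, yielding ``auc_norm``.  Fitting and
    transforming the same cohort reproduces the standard normalized AUC, in
    which the cohort-maximal organoid scores exactly 1 for each drug.

    Parameters
    ----------
    fit_ic50 : bool, default False
        Also run the 4PL fit per curve (slower; AUC does not need it).
    """

    def __init__(self, fit_ic50: bool = False):
        self.fit_ic50 = fit_ic50

    def fit(self, X: pd.DataFrame, y=None) -> "DoseResponseTransformer":
        curves = summarize_cohort(X, fit_ic50=False)
        self.max_auc_ = curves.groupby("drug")["auc_span"].max()
        if (self.max_auc_ <= 0).any():
            bad = self.max_auc_[self.max_auc_ <= 0].index.tolist()
            raise ValueError(f"cohort maximum AUC is zero for drugs {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "max_auc_"):
            raise ValueError("DoseResponseTransformer is not fitted")
        curves = summarize_cohort(X, fit_ic50=self.fit_ic50)
        curves["auc_norm"] = curves["auc_span"] / curves["drug"].map(self.max_auc_).to_numpy()
        return curves
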