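"""Quartile drug scores, regimen mapping and the organoid score.

For each drug, the cohort's normalized AUCs are cut at their quartiles
(linear-interpolation quantiles) and each organoid receives a drug score of
1-4: score 1 is the most sensitive quartile (lowest AUC), score 4 the most
resistant.  The organoid score for a patient is the arithmetic mean of the
drug scores of the screened drugs contained in that patient's clinical
regimen (n = number of scoreable regimen components); a score >= 2.5 defines
the high-risk class.

Regimen strings are resolved through an editable alias table: FOLFOX
contributes 5-FU and oxaliplatin, FOLFIRI contributes 5-FU and SN38
(irinotecan is scored via its active metabolite, the screened compound),
"+ Cetuximab" adds cetuximab, while bevacizumab is excluded as not evaluable
in organoids and components with no screened counterpart are excluded with
that reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Regimen",
    "DEFAULT_ALIASES",
    "NOT_EVALUABLE",
    "assign_drug_scores",
    "map_regimen",
    "organoid_score",
    "classify_risk",
    "select_refractory",
    "build_profiles",
    "QuartileDrugScorer",
]

DEFAULT_THRESHOLD = 2.5

NOT_EVALUABLE = "not evaluable in organoids"
NO_COUNTERPART = "no screened counterpart"

# component (lower-case) -> screened drug names, or an exclusion reason string
DEFAULT_ALIASES: dict[str, tuple[str, ...] | str] = {
    "folfox": ("5-FU", "oxaliplatin"),
    "folfiri": ("5-FU", "SN38"),
    "5-fu": ("5-FU",),
    "5-fluorouracil": ("5-FU",),
    "oxaliplatin": ("oxaliplatin",),
    "irinotecan": ("SN38",),
    "sn38": ("SN38",),
    "sn-38": ("SN38",),
    "cetuximab": ("cetuximab",),
    "bevacizumab": NOT_EVALUABLE,  # anti-angiogenic; no organoid counterpart
}


@dataclass(frozen=True)
class Regimen:
    """Scoreable decomposition of one clinical regimen string."""

    patient: str | None
    raw: str
    components: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]  # (component, reason)

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def scoreable(self) -> bool:
        return self.n >= 1


def assign_drug_scores(auc_norm: pd.Series,
                       quantiles: Sequence[float] = (0.25, 0.5, 0.75)
                       ) -> pd.Series:
    """Quartile drug score (1-4) per organoid for a single drug.

    Cut-points Q1-Q3 are linear-interpolation quantiles of the cohort's
    normalized AUC vector; a value <= Q1 scores 1, <= Q2 scores 2, <= Q3
    scores 3, else 4.  Tied values receive identical scores and the score is
    non-decreasing in ``auc_norm``.
    """
    vals = auc_norm.astype(float)
    if vals.size < 4:
        raise ValueError("need at least 4 organoids to form quartiles")
    bad = vals.index[~np.isfinite(vals)].tolist()
    if bad:
        raise ValueError(f"non-finite auc_norm for organoids {bad}")
    q1, q2, q3 = np.quantile(vals.to_numpy(), quantiles)
    scores = np.select(
        [vals <= q1, vals <= q2, vals <= q3], [1, 2, 3], default=4
    )
    return pd.Series(scores, index=vals.index, name="drug_score")


_SPLIT = re.compile(r"[+,/]")


def map_regimen(regimen: str, screened: Iterable[str],
                aliases: Mapping[str, tuple[str, ...] | str] | None = None,
                patient: str | None = None) -> Regimen:
    """Resolve a clinical regimen string to its scoreable screened drugs.

    Unknown components and components whose drugs were not screened are
    excluded with a reason; a regimen resolving to zero scoreable components
    is flagged not-scoreable rather than raising.
    """
    if not regimen or not regimen.strip():
        raise ValueError("empty regimen string")
    table = DEFAULT_ALIASES if aliases is None else aliases
    screened_set = set(screened)
    components: list[str] = []
    excluded: list[tuple[str, str]] = []
    for token in _SPLIT.split(regimen):
        token = token.strip()
        if not token:
            continue
        mapped = table.get(token.lower())
        if mapped is None:
            excluded.append((token, NO_COUNTERPART))
        elif isinstance(mapped, str):
            excluded.append((token, mapped))
        else:
            for drug in mapped:
                if drug in screened_set:
                    if drug not in components:
                        components.append(drug)
                else:
                    excluded.append((drug, NO_COUNTERPART))
    return Regimen(patient=patient, raw=regimen, components=tuple(components),
                   excluded=tuple(excluded))


def organoid_score(drug_scores: Iterable[float] | Mapping[str, float]) -> float:
    """Arithmetic mean of the component drug scores; value in [1, 4]."""
    if isinstance(drug_scores, Mapping):
        missing = [d for d, s in drug_scores.items() if s is None or not np.isfinite(s)]
        if missing:
            raise ValueError(f"missing drug score for components {missing}")
        vals = list(drug_scores.values())
    else:
        vals = list(drug_scores)
    if not vals:
        raise ValueError("organoid score needs at least one drug score")
    arr = np.asarray(vals, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite drug score")
    if ((arr < 1) | (arr > 4)).any():
        raise ValueError("drug scores must lie in [1, 4]")
    return float(arr.mean())


def classify_risk(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'high' iff score >= threshold (boundary inclusive on the high side)."""
    return "high" if score >= threshold else "low"


def select_refractory(profiles: pd.DataFrame, outcomes: pd.DataFrame,
                      threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """Organoids with organoid score >= threshold from progressing patients.

    The refractory subset carried into the repurposing screen: high-score
    organoids whose matched patient has progression recorded.
    """
    merged = profiles.merge(outcomes, left_on="organoid", right_on="patient",
                            how="inner")
    mask = (merged["organoid_score"] >= threshold) & merged["progression"].astype(bool)
    return merged.loc[mask, "organoid"].tolist()


class QuartileDrugScorer(BaseEstimator, TransformerMixin):
    """Cohort quartile cut-points per drug -> drug scores 1-4.

    ``fit`` takes a wide organoid x drug frame of normalized AUCs and learns
    the per-drug quartile cut-points (``quantiles_``); ``transform`` maps AUC
    values onto scores using those fitted cut-points, so new organoids are
    scored against the reference cohort.

    Parameters
    ----------
    quantiles : tuple of float, default (0.25, 0.5, 0.75)
        Probability levels of the cut-points (linear interpolation).
    """

    def __init__(self, quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75)):
        self.quantiles = quantiles

    def fit(self, X: pd.DataFrame, y=None) -> "QuartileDrugScorer":
        X = pd.DataFrame(X)
        if X.shape[0] < 4:
            raise ValueError("need at least 4 organoids to form quartiles")
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("non-finite auc_norm values")
        qs = np.quantile(X.to_numpy(dtype=float), self.quantiles, axis=0)
        self.quantiles_ = pd.DataFrame(qs, index=["q1", "q2", "q3"],
                                       columns=X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "quantiles_"):
            raise ValueError("QuartileDrugScorer is not fitted")
        X = pd.DataFrame(X)
        out = {}
        for drug in self.quantiles_.columns:
            v = X[drug].astype(float)
            q1, q2, q3 = self.quantiles_[drug]
            out[drug] = np.select([v <= q1, v <= q2, v <= q3], [1, 2, 3],
                                  default=4)
        return pd.DataFrame(out, index=X.index)


def build_profiles(auc_norm_wide: pd.DataFrame, clinical: pd.DataFrame,
                   threshold: float = DEFAULT_THRESHOLD,
                   aliases: Mapping[str, tuple[str, ...] | str] | None = None
                   ) -> pd.DataFrame:
    """Score a cohort: drug scores, regimen decomposition, organoid score.

    ``auc_norm_wide`` is organoid x drug normalized AUC; ``clinical`` supplies
    one regimen string per patient (patient ids match organoid ids).  Drug
    scores are assigned on the full cohort before any patient exclusion.
    Returns one row per organoid with per-drug scores, the scoreable
    components, n, the organoid score and the risk class (NaN score and empty
    class when no component is scoreable).
    """
    scorer = QuartileDrugScorer().fit(auc_norm_wide)
    scores = scorer.transform(auc_norm_wide)
    screened = list(auc_norm_wide.columns)
    clin = clinical.set_index("patient")
    rows = []
    for org in auc_norm_wide.index:
        row: dict = {"organoid": org}
        for drug in screened:
            row[f"score_{drug}"] = int(scores.loc[org, drug])
        if org in clin.index:
            reg = map_regimen(str(clin.loc[org, "regimen"]), screened,
                              aliases=aliases, patient=org)
            row["regimen"] = reg.raw
            row["components"] = "|".join(reg.components)
            row["n_components"] = reg.n
            if reg.scoreable:
                sc = organoid_score({d: scores.loc[org, d] for d in reg.components})
                row["organoid_score"] = sc
                row["risk_class"] = classify_risk(sc, threshold)
            else:
                row["organoid_score"] = np.nan
                row["risk_class"] = ""
        else:
            row.update(regimen="", components="", n_components=0,
                       organoid_score=np.nan, risk_class="")
        rows.append(row)
    return pd.DataFrame(rows)
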