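"""Association and survival statistics for score-outcome comparison.

Implements the statistical toolkit of the analysis: Spearman rank correlation
(exact permutation p at small n), the Kaplan-Meier product-limit estimator,
the two-group log-rank test with hypergeometric variance, the Mantel-Haenszel
hazard ratio derived from log-rank O/E/V, the Mann-Whitney U test and the
Kruskal-Wallis test.  ``associate_cohort`` chains them into the cohort-level
report: organoid score versus tumor-size change on the palliative subset, and
high- versus low-risk survival stratification at the 2.5 cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "LogrankResult",
    "HazardRatioResult",
    "spearman",
    "km_estimate",
    "logrank",
    "mh_hazard_ratio",
    "mann_whitney",
    "kruskal_wallis",
    "associate_cohort",
]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    method: str  # "exact-permutation" or "t-approximation"
    n: int


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    observed1: float
    expected1: float
    variance: float


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    method: str = "mantel-haenszel"


def spearman(x, y, *, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rho with exact permutation p for n <= ``exact_max_n``.

    Rho uses average ranks for ties.  The exact two-sided p enumerates all n!
    pairings of y against x and counts |rho| at least as extreme as observed;
    beyond ``exact_max_n`` the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # enumerate pairings; with standardized ranks rho is a dot product
        zx = (rx - rx.mean()) / rx.std()
        zy = (ry - ry.mean()) / ry.std()
        perms = np.array(list(permutations(range(n))))
        rhos = zy[perms] @ zx / n
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, "exact-permutation", n)
    t = rho * math.sqrt((n - 2) / max(1 - rho * rho, 1e-300))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), "t-approximation", n)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct event/censoring time with the at-risk count,
    number of events, and survival probability S(t); S is non-increasing with
    S(0) = 1 and censored subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times <= 0).any():
        raise ValueError("non-positive survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tab.index.to_numpy(dtype=float),
            "n_at_risk": tab["at_risk"].to_numpy(dtype=int),
            "n_events": tab["observed"].to_numpy(dtype=int),
            "n_censored": tab["censored"].to_numpy(dtype=int),
        }
    )
    out["survival"] = [float(surv.loc[t]) for t in out["time"]]
    return out


def _logrank_oev(times, events, group) -> tuple[float, float, float]:
    """Observed, expected and hypergeometric variance for group 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=int)
    o1 = e1 = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_j = at_risk.sum()
        n1_j = (at_risk & (group == 1)).sum()
        d_j = (events & (times == t)).sum()
        d1_j = (events & (times == t) & (group == 1)).sum()
        o1 += d1_j
        e1 += d_j * n1_j / n_j
        if n_j > 1:
            v += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    return float(o1), float(e1), float(v)


def logrank(times1, events1, times2, events2) -> LogrankResult:
    """Two-group log-rank test (ties pooled, hypergeometric variance).

    Group 1 is the first sample; p comes from chi-squared with 1 df.
    """
    t1 = np.asarray(times1, dtype=float)
    t2 = np.asarray(times2, dtype=float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([t1, t2])
    events = np.concatenate([np.asarray(events1, bool), np.asarray(events2, bool)])
    if not events.any():
        raise ValueError("need at least one event overall")
    group = np.concatenate([np.ones(t1.size, int), np.zeros(t2.size, int)])
    o1, e1, v = _logrank_oev(times, events, group)
    if v == 0:
        return LogrankResult(0.0, 1.0, o1, e1, v)
    chi2 = (o1 - e1) ** 2 / v
    return LogrankResult(float(chi2), float(sps.chi2.sf(chi2, 1)), o1, e1, v)


def mh_hazard_ratio(times1, events1, times2, events2, *,
                    method: str = "mantel-haenszel") -> HazardRatioResult:
    """Hazard ratio of group 1 versus group 2 from log-rank O/E/V.

    Default (Mantel-Haenszel / log-rank convention): HR = exp((O1 - E1)/V)
    with 95% CI exp((O1 - E1 +/- 1.96 sqrt(V))/V); HR > 1 means group 1
    progresses faster.  ``method="pike"`` gives the alternative
    (O1/E1)/(O2/E2) estimate with the same-variance CI.
    """
    e1_any = np.asarray(events1, bool).any()
    e2_any = np.asarray(events2, bool).any()
    if not (e1_any and e2_any):
        raise ValueError("both groups need at least one event")
    lr = logrank(times1, events1, times2, events2)
    o1, e1, v = lr.observed1, lr.expected1, lr.variance
    if v == 0:
        raise ValueError("zero log-rank variance: hazard ratio undefined")
    if method == "mantel-haenszel":
        log_hr = (o1 - e1) / v
    elif method == "pike":
        o2 = float(np.asarray(events2, bool).sum())
        e2 = (o1 + o2) - e1
        log_hr = math.log((o1 / e1) / (o2 / e2))
    else:
        raise ValueError(f"unknown method {method!r}")
    half = 1.96 * math.sqrt(v) / v
    return HazardRatioResult(math.exp(log_hr), math.exp(log_hr - half),
                             math.exp(log_hr + half), method)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (average-rank ties).

    Exact p by enumeration when n_a + n_b <= 16 and the data carry no ties;
    otherwise the tie-corrected normal approximation.  Returns (U_a, p) for
    the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi2 with k-1 df."""
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class AssociationReport:
    """Cohort association report mirroring the score-outcome analysis."""

    spearman: SpearmanResult | None
    logrank_palliative: LogrankResult | None
    hr_palliative: HazardRatioResult | None
    logrank_overall: LogrankResult | None
    hr_overall: HazardRatioResult | None
    km_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_palliative: int = 0
    n_overall: int = 0
    n_high_overall: int = 0
    n_low_overall: int = 0

    def to_dict(self) -> dict:
        def _sp(r):
            return None if r is None else dict(rho=r.rho, p=r.p, method=r.method, n=r.n)

        def _lr(r):
            return None if r is None else dict(chi2=r.chi2, p=r.p)

        def _hr(r):
            return None if r is None else dict(hr=r.hr, ci_low=r.ci_low, ci_high=r.ci_high)

        return {
            "spearman": _sp(self.spearman),
            "logrank_palliative": _lr(self.logrank_palliative),
            "hr_palliative": _hr(self.hr_palliative),
            "logrank_overall": _lr(self.logrank_overall),
            "hr_overall": _hr(self.hr_overall),
            "n_palliative": self.n_palliative,
            "n_overall": self.n_overall,
            "n_high_overall": self.n_high_overall,
            "n_low_overall": self.n_low_overall,
        }


_EXCLUDE_COLS = (
    "exclude_bsc",
    "exclude_low_concordance",
    "exclude_post_treatment",
    "exclude_lost_followup",
)


def _survival_pair(df: pd.DataFrame):
    high = df[df["risk_class"] == "high"]
    low = df[df["risk_class"] == "low"]
    if high.empty or low.empty:
        return None, None, {}
    args = (high["pfs_days"], high["event"], low["pfs_days"], low["event"])
    try:
        lr = logrank(*args)
    except ValueError:
        return None, None, {}
    try:
        hr = mh_hazard_ratio(*args)
    except ValueError:
        hr = None
    km = {
        "high": km_estimate(high["pfs_days"], high["event"]),
        "low": km_estimate(low["pfs_days"], low["event"]),
    }
    return lr, hr, km


def associate_cohort(profiles: pd.DataFrame, clinical: pd.DataFrame
                     ) -> AssociationReport:
    """Score-outcome association on an exclusion-filtered cohort.

    Merges profiles with the clinical table, drops patients carrying any
    exclusion flag (best supportive care, low organoid-tissue concordance,
    post-treatment sample, loss to follow-up) or without a scoreable regimen,
    then computes (i) Spearman of organoid score versus % tumor-size change
    on the palliative subset and (ii) Kaplan-Meier curves, log-rank test and
    Mantel-Haenszel HR for the high (>= 2.5) versus low risk classes, on the
    palliative subset and overall.
    """
    merged = profiles.merge(clinical, left_on="organoid", right_on="patient",
                            how="inner")
    excl = np.zeros(len(merged), dtype=bool)
    for col in _EXCLUDE_COLS:
        if col in merged.columns:
            excl |= merged[col].astype(bool)
    evaluable = merged[~excl & merged["organoid_score"].notna()].copy()
    evaluable = evaluable[evaluable["pfs_days"].notna()]
    palliative = evaluable[evaluable.get("setting", "") == "palliative"]

    pall_pairs = palliative[palliative["size_change_pct"].notna()]
    sp = None
    if len(pall_pairs) >= 3:
        try:
            sp = spearman(pall_pairs["organoid_score"], pall_pairs["size_change_pct"])
        except ValueError:
            sp = None
    lr_p, hr_p, km_p = _survival_pair(palliative)
    lr_o, hr_o, km_o = _survival_pair(evaluable)
    km_tables = {f"palliative_{k}": v for k, v in km_p.items()}
    km_tables.update({f"overall_{k}": v for k, v in km_o.items()})
    return AssociationReport(
        spearman=sp, logrank_palliative=lr_p, hr_palliative=hr_p,
        logrank_overall=lr_o, hr_overall=hr_o, km_tables=km_tables,
        n_palliative=len(palliative), n_overall=len(evaluable),
        n_high_overall=int((evaluable["risk_class"] == "high").sum()),
        n_low_overall=int((evaluable["risk_class"] == "low").sum()),
    )
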