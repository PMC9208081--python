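"""FDA-library repurposing-screen analysis for refractory organoids.

Operates on organoid x drug AUC matrices from duplicate screens of
standard-therapy-refractory organoids: replicate concordance (per-organoid
Pearson r across drugs, cohort median), per-drug Z-scores of the mean AUC
(standardized across organoids, so negative z = relatively sensitive),
within-target-class response agreement (mean pairwise correlation of member
drugs' z-vectors with a label-permutation null — this package's
formalization of the visual shared-target claim), and per-organoid candidate
ranking by ascending z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "replicate_concordance",
    "auc_zscore",
    "shared_target_agreement",
    "rank_candidates",
]


def replicate_concordance(screen1: pd.DataFrame, screen2: pd.DataFrame
                          ) -> tuple[pd.Series, float]:
    """Per-organoid Pearson r between duplicate screens, plus cohort median.

    Rows are organoids, columns drugs; the two matrices must share both index
    sets.  Pearson r is computed across drugs within each organoid.
    """
    if list(screen1.index) != list(screen2.index) or \
            list(screen1.columns) != list(screen2.columns):
        raise ValueError("replicate screens must share identical rows and columns")
    if screen1.shape[1] < 3:
        raise ValueError("need at least 3 drugs for replicate concordance")
    rs = {}
    for org in screen1.index:
        x = screen1.loc[org].to_numpy(dtype=float)
        y = screen2.loc[org].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in replicate vector for {org!r}")
        rs[org] = float(sps.pearsonr(x, y).statistic)
    per_org = pd.Series(rs, name="pearson_r")
    return per_org, float(per_org.median())


def auc_zscore(auc: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize AUC per drug across organoids (sample sd, ddof=1).

    Returns the z matrix and the list of drugs flagged undefined (zero
    variance columns, left as NaN).  Negative z marks a relatively sensitive
    organoid-drug pair.
    """
    if auc.shape[0] < 3:
        raise ValueError("need at least 3 organoids per drug for z-scores")
    vals = auc.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flagged = [str(d) for d, s in zip(auc.columns, sd) if s == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    z[:, sd == 0] = np.nan
    return pd.DataFrame(z, index=auc.index, columns=auc.columns), flagged


def _mean_pairwise_r(z: pd.DataFrame, members: list[str]) -> float:
    sub = z[members].to_numpy(dtype=float)
    corr = np.corrcoef(sub, rowvar=False)
    iu = np.triu_indices(len(members), k=1)
    return float(np.nanmean(corr[iu]))


def shared_target_agreement(z: pd.DataFrame,
                            target_map: dict[str, list[str] | tuple[str, ...]],
                            *, n_permutations: int = 1000,
                            seed: int | np.random.Generator = 0
                            ) -> pd.DataFrame:
    """Within-class mean pairwise correlation with a permutation null.

    For each target class with >= 2 member drugs, computes the mean pairwise
    Pearson r of the member drugs' z-vectors across organoids.  The null
    reassigns class labels (of the same sizes) uniformly at random over all
    class-labelled drugs, ``n_permutations`` times; p is the one-sided
    (larger-agreement) permutation p with the +1 correction.  Singleton
    classes are reported with a note and no statistic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = {c: [d for d in ms if d in z.columns] for c, ms in target_map.items()}
    labelled = sorted({d for ms in classes.values() for d in ms})
    rows = []
    for cls, members in classes.items():
        if len(members) < 2:
            rows.append(dict(target_class=cls, n_drugs=len(members),
                             mean_pairwise_r=np.nan, p=np.nan,
                             note="skipped: fewer than 2 member drugs"))
            continue
        obs = _mean_pairwise_r(z, members)
        count = 0
        k = len(members)
        for _ in range(n_permutations):
            perm = rng.permutation(labelled)[:k].tolist()
            if _mean_pairwise_r(z, perm) >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        rows.append(dict(target_class=cls, n_drugs=k, mean_pairwise_r=obs,
                         p=p, note=""))
    return pd.DataFrame(rows)


def rank_candidates(z: pd.DataFrame, auc: pd.DataFrame, organoid: str,
                    genotype: pd.Series | dict | None = None,
                    porcn_drug: str = "LGK974") -> pd.DataFrame:
    """Ordered repurposing candidates for one organoid.

    Drugs sort by ascending z (most relatively sensitive first), ties broken
    by ascending absolute AUC, then drug name for a deterministic total
    order.  When genotype flags are supplied, the report annotates
    genotype-consistent hits (RNF43 loss-of-function with a sensitive
    porcupine-inhibitor response).
    """
    if organoid not in z.index:
        raise KeyError(f"organoid {organoid!r} not in z matrix")
    zi = z.loc[organoid]
    ai = auc.loc[organoid]
    out = pd.DataFrame({"drug": z.columns, "z": zi.to_numpy(),
                        "auc_span": ai.reindex(z.columns).to_numpy()})
    out["abs_auc"] = out["auc_span"].abs()
    out = out.sort_values(["z", "abs_auc", "drug"], kind="mergesort",
                          na_position="last").drop(columns="abs_auc")
    out["rank"] = np.arange(1, len(out) + 1)
    notes = []
    rnf43 = bool(genotype["rnf43_lof"]) if genotype is not None else False
    for drug, zval in zip(out["drug"], out["z"]):
        if rnf43 and drug == porcn_drug and np.isfinite(zval) and zval < 0:
            notes.append("genotype-consistent: RNF43 LoF, sensitive to PORCN inhibitor")
        else:
            notes.append("")
    out["note"] = notes
    return out.reset_index(drop=True)
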