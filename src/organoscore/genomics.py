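"""Variant-level utilities: concordance, mutation burden, genotype flags.

Consumes variant calls (VCF plus effect annotations from INFO fields or a
sidecar table) and provides the three genomic quantities the screen analysis
needs: organoid-tissue variant concordance (shared / union, with SNV and
indel breakdown), mutation burden per megabase with the >10/Mb hypermutation
rule, and therapy-relevant genotype flags — anti-EGFR resistance hotspots
(KRAS/NRAS codons 12/13/61, BRAF V600E, PIK3CA E545K/H1047R), RNF43
loss-of-function (predictive of porcupine-inhibitor sensitivity) and APC
truncation.  Variant calling and effect annotation themselves are upstream
and never reimplemented here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "GenotypeFlags",
    "ConcordanceResult",
    "MutationRateResult",
    "normalize_variant",
    "load_variants",
    "concordance",
    "mutation_rate",
    "genotype_flags",
    "compare_auc_by_genotype",
    "HYPERMUTATION_THRESHOLD",
]

HYPERMUTATION_THRESHOLD = 10.0  # mutations per Mb; strict inequality

_RAS_HOTSPOT_CODONS = {12, 13, 61}
_BRAF_HOTSPOTS = {"V600E"}
_PIK3CA_HOTSPOTS = {"E545K", "H1047R"}
_LOF_CLASSES = {"frameshift", "nonsense", "homozygous_deletion"}

_PROTEIN_RE = re.compile(r"^([A-Za-z])(\d+)")


@dataclass(frozen=True)
class VariantCall:
    """One normalized variant call keyed by (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect_class: str = "unknown"  # missense, frameshift, nonsense, silent, ...
    protein_change: str = ""
    vaf: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def silent(self) -> bool:
        return self.effect_class in {"silent", "synonymous"}


@dataclass(frozen=True)
class GenotypeFlags:
    """Therapy-relevant genotype summary with supporting evidence."""

    anti_egfr_resistant: bool
    rnf43_lof: bool
    apc_truncating: bool
    evidence: tuple[tuple[str, str, float | None], ...]  # (gene, p-change, VAF)


@dataclass(frozen=True)
class ConcordanceResult:
    overall_pct: float
    snv_pct: float | None
    indel_pct: float | None
    shared: int
    a_only: int
    b_only: int


@dataclass(frozen=True)
class MutationRateResult:
    per_mb: float
    n_silent: int
    n_nonsilent: int
    hypermutated: bool


def normalize_variant(chrom: str, pos: int, ref: str, alt: str
                      ) -> tuple[str, int, str, str]:
    """Normalize a call: strip 'chr' prefix, left-align, make parsimonious.

    Shared trailing bases are trimmed first, then shared leading bases (the
    position advances), keeping at least one base on each allele — so
    different caller dialects of the same indel agree on one key.
    """
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _annotation_lookup(annotations: pd.DataFrame | None):
    if annotations is None:
        return {}
    idx = {}
    for row in annotations.itertuples(index=False):
        key = normalize_variant(str(row.chrom), int(row.pos), str(row.ref),
                                str(row.alt))
        vaf = getattr(row, "vaf", None)
        idx[key] = (
            str(getattr(row, "gene", "") or ""),
            str(getattr(row, "effect_class", "unknown") or "unknown"),
            str(getattr(row, "protein_change", "") or ""),
            float(vaf) if vaf is not None and np.isfinite(vaf) else None,
        )
    return idx


def load_variants(vcf_path: str | Path,
                  annotations: pd.DataFrame | None = None) -> list[VariantCall]:
    """Read a VCF into normalized, deduplicated :class:`VariantCall` records.

    Effect annotations are taken from INFO fields ``GENE``, ``CLASS``,
    ``PCHANGE`` and ``VAF`` when present, else from the ``annotations``
    sidecar table (columns chrom, pos, ref, alt, gene, effect_class,
    protein_change, vaf).  Calls missing any annotation get effect 'unknown'
    with a logged warning.
    """
    from cyvcf2 import VCF

    lookup = _annotation_lookup(annotations)
    seen: dict[tuple, VariantCall] = {}
    n_unannotated = 0
    for rec in VCF(str(vcf_path)):
        for alt in rec.ALT or []:
            key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
            if key in seen:
                continue
            gene = rec.INFO.get("GENE")
            eff = rec.INFO.get("CLASS")
            pch = rec.INFO.get("PCHANGE")
            vaf = rec.INFO.get("VAF")
            if gene is None and key in lookup:
                gene, eff, pch, vaf = lookup[key]
            if eff is None:
                n_unannotated += 1
                eff = "unknown"
            seen[key] = VariantCall(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                gene=str(gene or ""), effect_class=str(eff),
                protein_change=str(pch or ""),
                vaf=float(vaf) if vaf is not None else None,
            )
    if n_unannotated:
        logger.warning("%d variant(s) missing effect annotation; set to 'unknown'",
                       n_unannotated)
    return list(seen.values())


def _keys(calls: Iterable[VariantCall] | Iterable[tuple]) -> set[tuple]:
    out = set()
    for c in calls:
        out.add(c.key if isinstance(c, VariantCall) else tuple(c))
    return out


def _is_snv(key: tuple) -> bool:
    return len(key[2]) == 1 and len(key[3]) == 1


def concordance(organoid_calls, tissue_calls, *,
                denominator: str = "union") -> ConcordanceResult:
    """Variant concordance between an organoid and its matched tissue.

    Default: concordance = 100 * |shared| / |union| (symmetric), with
    per-type SNV and indel breakdowns (None for a type absent from both
    samples).  ``denominator="tissue"`` divides by the tissue call count
    instead (asymmetric: the fraction of tissue calls recovered in the
    organoid).
    """
    if denominator not in ("union", "tissue"):
        raise ValueError(f"unknown denominator {denominator!r}")
    a, b = _keys(organoid_calls), _keys(tissue_calls)
    if not a and not b:
        raise ValueError("both call sets are empty: concordance undefined")

    def _pct(sa: set, sb: set) -> float | None:
        denom = sa | sb if denominator == "union" else sb
        if not denom:
            return None
        return 100.0 * len(sa & sb) / len(denom)

    snv_a = {k for k in a if _is_snv(k)}
    snv_b = {k for k in b if _is_snv(k)}
    return ConcordanceResult(
        overall_pct=_pct(a, b),
        snv_pct=_pct(snv_a, snv_b),
        indel_pct=_pct(a - snv_a, b - snv_b),
        shared=len(a & b),
        a_only=len(a - b),
        b_only=len(b - a),
    )


def mutation_rate(calls: Iterable[VariantCall], callable_mb: float
                  ) -> MutationRateResult:
    """Mutations per megabase of callable territory; hypermutated iff > 10/Mb."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    calls = list(calls)
    n_silent = sum(1 for c in calls if c.silent)
    rate = len(calls) / callable_mb
    return MutationRateResult(
        per_mb=rate, n_silent=n_silent, n_nonsilent=len(calls) - n_silent,
        hypermutated=rate > HYPERMUTATION_THRESHOLD,
    )


def _codon(protein_change: str) -> int | None:
    m = _PROTEIN_RE.match(protein_change)
    return int(m.group(2)) if m else None


def genotype_flags(calls: Iterable[VariantCall]) -> GenotypeFlags:
    """Therapy-relevant flags from a call set (pure, order-invariant).

    anti_egfr_resistant: any KRAS/NRAS codon 12/13/61 missense, BRAF V600E or
    PIK3CA E545K/H1047R.  rnf43_lof: RNF43 frameshift/nonsense/homozygous
    deletion.  apc_truncating: APC nonsense/frameshift.  VAFs ride along as
    evidence for manual review (e.g. a high-VAF RNF43 frameshift next to a
    low-VAF APC point mutation is reported, never auto-adjudicated).
    """
    anti_egfr = rnf43 = apc = False
    evidence: list[tuple[str, str, float | None]] = []
    for c in sorted(calls, key=lambda c: c.key):
        gene = c.gene.upper()
        hit = False
        if gene in ("KRAS", "NRAS") and c.effect_class == "missense":
            if _codon(c.protein_change) in _RAS_HOTSPOT_CODONS:
                anti_egfr = hit = True
        elif gene == "BRAF" and c.protein_change in _BRAF_HOTSPOTS:
            anti_egfr = hit = True
        elif gene == "PIK3CA" and c.protein_change in _PIK3CA_HOTSPOTS:
            anti_egfr = hit = True
        if gene == "RNF43" and c.effect_class in _LOF_CLASSES:
            rnf43 = hit = True
        if gene == "APC" and c.effect_class in {"nonsense", "frameshift"}:
            apc = hit = True
        if hit:
            evidence.append((c.gene, c.protein_change, c.vaf))
    return GenotypeFlags(anti_egfr, rnf43, apc, tuple(evidence))


def compare_auc_by_genotype(auc_norm: pd.Series,
                            flags: Mapping[str, bool] | pd.Series,
                            ) -> dict:
    """Mann-Whitney of normalized AUC between flagged and unflagged organoids.

    ``auc_norm`` is indexed by organoid for one drug; ``flags`` maps organoid
    to a boolean genotype flag.  Raises when either genotype group is empty.
    """
    flags = pd.Series(flags)
    common = auc_norm.index.intersection(flags.index)
    flagged = auc_norm.loc[[o for o in common if flags[o]]]
    unflagged = auc_norm.loc[[o for o in common if not flags[o]]]
    if flagged.empty or unflagged.empty:
        raise ValueError("both genotype groups must be non-empty")
    u, p = mann_whitney(flagged.to_numpy(), unflagged.to_numpy())
    return {
        "statistic": "mann-whitney U",
        "U": u,
        "p": p,
        "n_flagged": int(flagged.size),
        "n_unflagged": int(unflagged.size),
        "median_flagged": float(flagged.median()),
        "median_unflagged": float(unflagged.median()),
    }
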