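"""Site-level hard filters, genotype acceptance rules, call-set metrics.

The hard-filter labels mirror the GATK-style thresholds applied upstream of
this pipeline; all comparisons are strict, exactly as the labels are written,
and a missing metric never triggers its clause.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import Cohort, GenotypeCall, VariantKey, VariantSite

__all__ = [
    "SNV_FILTERS", "INDEL_FILTERS",
    "apply_site_filters", "qc_genotype", "apply_genotype_qc",
    "filter_sites", "variant_set_metrics", "VariantSetMetrics",
]

# (metric, op, threshold); op "<" fails when value < threshold, ">" when >
SNV_FILTERS = (
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("HaplotypeScore", ">", 13.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)
INDEL_FILTERS = (
    ("QD", "<", 2.0),
    ("ReadPosRankSum", "<", -20.0),
    ("InbreedingCoeff", "<", -0.8),
    ("FS", ">", 200.0),
)


def apply_site_filters(site: VariantSite) -> tuple[bool, list[str]]:
    """Return (passes, reasons); reasons list every violated clause."""
    rules = SNV_FILTERS if site.variant_class == "SNV" else INDEL_FILTERS
    reasons = []
    for name, op, thr in rules:
        val = site.site_metrics.get(name)
        if val is None:
            continue
        if (op == "<" and val < thr) or (op == ">" and val > thr):
            reasons.append(f"{name} {op} {thr}")
    return (not reasons), reasons


def qc_genotype(call: GenotypeCall, min_depth: int = 4,
                het_alt_ratio: float = 0.25, hom_ratio: float = 0.95,
                het_depth_mode: str = "total") -> tuple[bool, str | None]:
    """Genotype acceptance: (keep, reason-if-set-missing).

    Heterozygotes are kept only when supported by more than ``min_depth``
    reads with alt-allele ratio above ``het_alt_ratio``; homozygotes when the
    supporting-allele ratio is above ``hom_ratio``.  All bounds are strict.
    ``het_depth_mode`` selects whether the het read-support requirement is on
    the total site depth ("total", default) or on the alt-supporting reads
    ("alt") — the source description is ambiguous and both are implemented.
    """
    if call.is_missing:
        return True, None
    if call.depth_total is None or call.depth_alt is None:
        return False, "no depth"
    dp, ad = call.depth_total, call.depth_alt
    if call.is_het:
        support = ad if het_depth_mode == "alt" else dp
        if support <= min_depth:
            return False, f"het support {support} <= {min_depth}"
        if dp == 0 or ad / dp <= het_alt_ratio:
            return False, f"het alt ratio <= {het_alt_ratio}"
        return True, None
    # homozygote (ref or alt): supporting allele = the called allele
    support_reads = ad if call.dosage == 2 else dp - ad
    if dp <= min_depth:
        return False, f"hom depth {dp} <= {min_depth}"
    if support_reads / dp <= hom_ratio:
        return False, f"hom allele ratio <= {hom_ratio}"
    return True, None


def apply_genotype_qc(cohort: Cohort, min_depth: int = 4,
                      het_alt_ratio: float = 0.25, hom_ratio: float = 0.95,
                      het_depth_mode: str = "total") -> int:
    """Vectorized genotype QC over the cohort; failing calls become missing.

    Returns the number of genotypes set missing.  Variant keys and order are
    never altered.
    """
    gt, dp, ad = cohort.gt, cohort.dp, cohort.ad
    called = gt >= 0
    no_depth = called & ((dp < 0) | (ad < 0))
    dp_safe = np.maximum(dp, 1)
    alt_ratio = ad / dp_safe
    het = called & (gt == 1)
    hom = called & (gt != 1)
    support = ad if het_depth_mode == "alt" else dp
    het_fail = het & ((support <= min_depth) | (alt_ratio <= het_alt_ratio))
    hom_support = np.where(gt == 2, ad, dp - ad)
    hom_fail = hom & ((dp <= min_depth) | (hom_support / dp_safe <= hom_ratio))
    fail = no_depth | (het_fail & ~no_depth) | (hom_fail & ~no_depth)
    cohort.gt = np.where(fail, np.int8(-1), gt)
    return int(fail.sum())


def filter_sites(cohort: Cohort, drop_non_pass: bool = False
                 ) -> tuple[Cohort, dict[VariantKey, list[str]]]:
    """Apply the hard site filters, returning (passing cohort, fail reasons).

    With ``drop_non_pass``, records whose VCF FILTER column is not PASS are
    removed before the hard filters (recalibration upstream is not modelled
    here; its verdict is consumed from the FILTER column when present).
    """
    reasons: dict[VariantKey, list[str]] = {}
    keep = []
    for i, v in enumerate(cohort.variants):
        if drop_non_pass and v.filter_label not in ("PASS", ".", ""):
            reasons[v.key] = [f"FILTER {v.filter_label}"]
            continue
        ok, why = apply_site_filters(v)
        if ok:
            keep.append(i)
        else:
            reasons[v.key] = why
    return cohort.subset_variants(keep), reasons


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class VariantSetMetrics:
    n_variants: int
    fraction_known: float | None
    ti_tv: float | None        # None when undefined (no SNVs); inf allowed

    @property
    def undefined(self) -> bool:
        return self.n_variants == 0


def variant_set_metrics(variants: list[VariantSite],
                        known_sites: set[VariantKey]) -> VariantSetMetrics:
    """Call-set evaluation: size, known-site coverage and Ti/Tv over SNVs."""
    n = len(variants)
    if n == 0:
        return VariantSetMetrics(0, None, None)
    known = sum(v.key in known_sites for v in variants)
    ti = tv = 0
    for v in variants:
        if v.variant_class != "SNV":
            continue
        if (v.ref, v.alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        titv: float | None = None
    elif tv == 0:
        titv = math.inf
    else:
        titv = ti / tv
    return VariantSetMetrics(n, known / n, titv)
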