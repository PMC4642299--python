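"""The rare-damaging filtering cascade.

Per-variant predicates (exonic, rare in every frequency resource, damaging by
consequence/predictor vote) are order-insensitive; the cross-family identical-
variant exclusion is the single cohort-level predicate and runs last, because
identical rare "damaging" alleles recurring across unrelated families are far
more likely platform artifacts than independent mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (Cohort, FrequencyResource, PredictionScores,
                      VariantKey, VariantSite)

__all__ = [
    "is_rare", "classify_damaging", "exclude_cross_family_recurrent",
    "filter_cascade", "FilterResult", "FamilySummaryRow",
]

EXONIC_CONSEQUENCES = ("LOF", "missense", "synonymous")


def is_rare(site: VariantSite, resources: list[FrequencyResource],
            threshold: float = 0.01) -> bool:
    """True iff MAF < threshold in every resource (absent = not observed = rare)."""
    if not resources:
        raise ValueError("at least one frequency resource is required")
    for res in resources:
        maf = res.get(site.key)
        if maf is not None and maf >= threshold:
            return False
    return True


def classify_damaging(site: VariantSite, scores: PredictionScores,
                      min_votes: int = 3) -> bool:
    """Consensus damaging call.

    Loss-of-function variants are damaging outright; synonymous variants never
    are; missense variants are damaging when at least ``min_votes`` of the
    non-unknown predictor calls vote damaging.
    """
    if site.consequence == "LOF":
        return True
    if site.consequence != "missense":
        return False
    calls = scores.get(site.key)
    votes = sum(1 for c in calls.values() if c == "damaging")
    return votes >= min_votes


def exclude_cross_family_recurrent(variant_key: VariantKey,
                                   family_presence: dict[str, bool]) -> bool:
    """True = keep; exclude when the identical variant is in >= 2 families."""
    return sum(bool(v) for v in family_presence.values()) < 2


@dataclass
class FamilySummaryRow:
    """One family of the per-family summary (per-patient counts, sharing)."""

    family_id: str
    per_patient: dict[str, int]
    n_shared: int
    n_shared_lof: int


@dataclass
class FilterResult:
    """Output of the cascade: kept variant indices and per-patient lists."""

    kept_idx: np.ndarray                       # indices into cohort.variants
    per_patient: dict[str, np.ndarray]         # affected sample -> kept indices
    family_rows: list[FamilySummaryRow]
    excluded_recurrent: list[VariantKey] = field(default_factory=list)
    n_exonic: int = 0
    n_rare: int = 0
    n_damaging: int = 0


def _per_variant_mask(cohort: Cohort, resources, scores, threshold, min_votes):
    exonic = np.array([v.consequence in EXONIC_CONSEQUENCES
                       for v in cohort.variants], dtype=bool)
    rare = np.array([is_rare(v, resources, threshold)
                     for v in cohort.variants], dtype=bool)
    damaging = np.array([classify_damaging(v, scores, min_votes)
                         for v in cohort.variants], dtype=bool)
    return exonic, rare, damaging


def filter_cascade(cohort: Cohort, resources: list[FrequencyResource],
                   scores: PredictionScores, threshold: float = 0.01,
                   min_votes: int = 3,
                   exclude_recurrent: bool = True) -> FilterResult:
    """Produce each patient's rare-damaging variant list and a family summary.

    Order: exonic restriction -> rarity -> damaging consensus -> cross-family
    identical-variant exclusion.  A family "carries" a variant for the
    exclusion step when any member, affected or not, carries the alt allele.
    Patients are the genotyped affected samples of the attached pedigree.
    """
    if cohort.pedigree is None:
        raise ValueError("cohort has no attached pedigree")
    ped = cohort.pedigree

    exonic, rare, damaging = _per_variant_mask(
        cohort, resources, scores, threshold, min_votes)
    keep = exonic & rare & damaging

    carrier = cohort.carrier_mask()            # variants x samples
    sample_family = np.array([ped.family_of(s) if s in ped.members else ""
                              for s in cohort.samples])
    families = [f for f in ped.families
                if any(sf == f for sf in sample_family)]

    excluded: list[VariantKey] = []
    if exclude_recurrent and len(families) > 1:
        fam_presence = np.zeros((cohort.n_variants, len(families)), dtype=bool)
        for fi, fam in enumerate(families):
            cols = np.flatnonzero(sample_family == fam)
            if cols.size:
                fam_presence[:, fi] = carrier[:, cols].any(axis=1)
        recurrent = keep & (fam_presence.sum(axis=1) >= 2)
        excluded = [cohort.variants[i].key for i in np.flatnonzero(recurrent)]
        keep = keep & ~recurrent

    kept_idx = np.flatnonzero(keep)

    per_patient: dict[str, np.ndarray] = {}
    family_rows: list[FamilySummaryRow] = []
    lof = np.array([v.is_lof for v in cohort.variants], dtype=bool)
    for fam in ped.families:
        aff = [s for s in ped.affected(fam) if s in cohort._sample_index]
        if not aff:
            continue
        counts = {}
        aff_cols = []
        for s in aff:
            j = cohort.sample_index(s)
            aff_cols.append(j)
            mine = keep & carrier[:, j]
            per_patient[s] = np.flatnonzero(mine)
            counts[s] = int(mine.sum())
        shared = keep & carrier[:, aff_cols].all(axis=1)
        family_rows.append(FamilySummaryRow(
            family_id=fam, per_patient=counts,
            n_shared=int(shared.sum()),
            n_shared_lof=int((shared & lof).sum())))

    return FilterResult(
        kept_idx=kept_idx, per_patient=per_patient, family_rows=family_rows,
        excluded_recurrent=excluded,
        n_exonic=int(exonic.sum()), n_rare=int((exonic & rare).sum()),
        n_damaging=int((exonic & rare & damaging).sum()))
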