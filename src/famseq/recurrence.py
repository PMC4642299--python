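"""Cross-family gene recurrence and sharing/burden statistics.

The statistics here are fully specified stand-ins for the external
linkage/association tools used in the original analysis: a per-family rare-
variant sharing probability under null Mendelian transmission, an exact
Poisson-binomial combination across families, a sharing LOD, and an exact
hypergeometric carrier-table (burden) test against background genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .core_io import Cohort, CohortFixture, VariantKey
from .pedigree import Pedigree
from .rare_damaging import FilterResult

__all__ = [
    "GeneRecurrenceResult", "SharingProbability",
    "recurrent_genes", "gene_sharing_table", "recurrence_from_fixture",
    "sharing_null_probability", "cross_family_sharing_pvalue", "sharing_lod",
    "attach_sharing_statistics", "burden_test", "bonferroni",
]


@dataclass
class GeneRecurrenceResult:
    """Per-gene recurrence record (the recurrent-gene table's row)."""

    gene: str
    families_shared: frozenset[str]        # all affected carry a shared variant
    families_single: tuple[tuple[str, str], ...]  # (family, patient) singles
    n_variants: int
    p_value: float | None = None           # sharing p (or table-reported p)
    lod: float | None = None
    p_burden: float | None = None
    p_adjusted: float | None = None
    bonferroni_significant: bool | None = None

    def __post_init__(self):
        single_fams = {f for f, _ in self.families_single}
        if self.families_shared & single_fams:
            raise ValueError(f"{self.gene}: a family cannot be both shared "
                             "and single-patient")
        if self.n_variants < len(self.families_shared):
            raise ValueError(f"{self.gene}: fewer variants than sharing families")

    @property
    def families(self) -> frozenset[str]:
        return self.families_shared | {f for f, _ in self.families_single}


# ---------------------------------------------------------------------------
# gene-level recurrence from a filtered cohort
# ---------------------------------------------------------------------------

def gene_sharing_table(cohort: Cohort, filt: FilterResult) -> dict[str, dict]:
    """Per-gene carrier/sharing structure over the filtered variant set.

    For each annotated gene: ``carrier_families`` (>= 1 affected carries a
    variant of the gene), ``shared_families`` (some single variant carried by
    every affected), ``singles`` ((family, patient) for carrier families
    without sharing) and ``variants`` (distinct keys carried by affecteds).
    """
    ped = cohort.pedigree
    if ped is None:
        raise ValueError("cohort has no attached pedigree")
    out: dict[str, dict] = {}
    fam_aff = {fam: [a for a in ped.affected(fam) if a in cohort._sample_index]
               for fam in ped.families}
    for i in filt.kept_idx:
        v = cohort.variants[int(i)]
        if not v.gene:
            continue
        rec = out.setdefault(v.gene, {
            "carrier_families": set(), "shared_families": set(),
            "singles": set(), "variants": set()})
        for fam, aff in fam_aff.items():
            if not aff:
                continue
            gts = [int(cohort.gt[int(i), cohort.sample_index(a)]) for a in aff]
            carriers = [a for a, g in zip(aff, gts) if g > 0]
            if not carriers:
                continue
            rec["carrier_families"].add(fam)
            rec["variants"].add(v.key)
            if len(carriers) == len(aff):      # every affected carries it
                rec["shared_families"].add(fam)
            else:
                for a in carriers:
                    rec["singles"].add((fam, a))
    for rec in out.values():
        rec["singles"] = {(f, a) for f, a in rec["singles"]
                          if f not in rec["shared_families"]}
    return out


def recurrent_genes(cohort: Cohort, filt: FilterResult
                    ) -> list[GeneRecurrenceResult]:
    """Genes whose variants are shared by both affecteds in >= 2 families."""
    table = gene_sharing_table(cohort, filt)
    results = []
    for gene in sorted(table):
        rec = table[gene]
        if len(rec["shared_families"]) < 2:
            continue
        results.append(GeneRecurrenceResult(
            gene=gene,
            families_shared=frozenset(rec["shared_families"]),
            families_single=tuple(sorted(rec["singles"])),
            n_variants=len(rec["variants"])))
    return results


def recurrence_from_fixture(fixture: CohortFixture
                            ) -> list[GeneRecurrenceResult]:
    """Recurrence records rebuilt from the packaged worked-example tables."""
    results = []
    for row in fixture.recurrent_genes:
        results.append(GeneRecurrenceResult(
            gene=row["gene"],
            families_shared=frozenset(row["families_shared"]),
            families_single=tuple((f, p) for f, p in row["families_single"]),
            n_variants=row["n_variants"],
            p_value=row["p_value"], lod=row["lod"]))
    return results


# ---------------------------------------------------------------------------
# sharing probability under null transmission
# ---------------------------------------------------------------------------

@dataclass
class SharingProbability:
    family_id: str
    p: float
    method: str                 # exact | monte_carlo
    degenerate: bool = False    # an affected member is a pedigree founder


def _transmission_probs(ped: Pedigree, family_id: str, source: str,
                        affected: list[str]) -> tuple[float, float]:
    """P(all affected carry) and P(>=1 affected carries) for one founder origin.

    The rare allele sits on a single copy in ``source``; each child of a
    carrier inherits it with probability 1/2 per carrier parent.  Exact by
    depth-first enumeration of carrier configurations (branching only below
    carriers, so cost is far below 2^n in practice).
    """
    order = [i for i in ped.topological(family_id) if not ped.member(i).is_founder]
    aff = set(affected)
    p_all = 0.0
    p_any = 0.0

    def rec(i: int, carriers: set[str], prob: float):
        nonlocal p_all, p_any
        if i == len(order):
            hit = aff & carriers
            if hit:
                p_any += prob
                if hit == aff:
                    p_all += prob
            return
        child = order[i]
        n_carrier_parents = sum(1 for p_ in ped.parents(child)
                                if p_ is not None and p_ in carriers)
        p_carry = 1.0 - 0.5 ** n_carrier_parents
        if p_carry > 0.0:
            rec(i + 1, carriers | {child}, prob * p_carry)
        if p_carry < 1.0:
            rec(i + 1, carriers, prob * (1.0 - p_carry))

    rec(0, {source}, 1.0)
    return p_all, p_any


def sharing_null_probability(ped: Pedigree, family_id: str,
                             method: str = "exact", n_drops: int = 100_000,
                             seed: int = 0,
                             max_exact_nonfounders: int = 18
                             ) -> SharingProbability:
    """P(all affected carry a single-founder-copy rare allele | >= 1 carries).

    The founder origin is enumerated uniformly over founder copies.  When an
    affected member is itself a founder, the origin is conditioned to be that
    founder (any shared allele must descend from it) and the result is flagged
    degenerate.  Exact enumeration for pedigrees up to
    ``max_exact_nonfounders`` non-founders, otherwise Monte-Carlo gene
    dropping with a fixed seed.
    """
    affected = ped.affected(family_id)
    if len(affected) < 1:
        raise ValueError(f"family {family_id!r} has no affected members")
    founders = ped.founders(family_id)
    aff_founders = [a for a in affected if ped.member(a).is_founder]
    if len(aff_founders) > 1:
        raise ValueError(f"family {family_id!r}: multiple affected founders; "
                         "a single rare founder copy cannot be shared")
    degenerate = bool(aff_founders)
    sources = aff_founders if degenerate else founders

    n_nonf = len(ped.nonfounders(family_id))
    if method == "exact" or (method == "auto" and n_nonf <= max_exact_nonfounders):
        num = den = 0.0
        for src in sources:       # founder copies are symmetric within a founder
            p_all, p_any = _transmission_probs(ped, family_id, src, affected)
            num += p_all
            den += p_any
        if den == 0.0:
            raise ValueError(f"family {family_id!r}: no affected member is "
                             f"reachable from any founder")
        return SharingProbability(family_id, num / den, "exact", degenerate)
    return _sharing_mc(ped, family_id, sources, affected, degenerate,
                       n_drops, seed)


def _sharing_mc(ped: Pedigree, family_id: str, sources: list[str],
                affected: list[str], degenerate: bool, n_drops: int,
                seed: int) -> SharingProbability:
    """Monte-Carlo gene-dropping estimate of the sharing probability."""
    rng = np.random.default_rng(seed)
    order = ped.topological(family_id)
    src_pick = rng.integers(0, len(sources), size=n_drops)
    carrier: dict[str, np.ndarray] = {}
    for iid in order:
        m = ped.member(iid)
        if m.is_founder:
            col = np.zeros(n_drops, dtype=bool)
            for si, s in enumerate(sources):
                if s == iid:
                    col |= src_pick == si
            carrier[iid] = col
        else:
            keep = np.zeros(n_drops, dtype=bool)
            for parent in ped.parents(iid):
                if parent is None:
                    continue
                transmit = rng.random(n_drops) < 0.5
                keep |= carrier[parent] & transmit
            carrier[iid] = keep
    aff_mat = np.stack([carrier[a] for a in affected])
    any_c = aff_mat.any(axis=0)
    all_c = aff_mat.all(axis=0)
    n_any = int(any_c.sum())
    if n_any == 0:
        raise ValueError(f"family {family_id!r}: no drop reached an affected")
    return SharingProbability(family_id, float(all_c.sum()) / n_any,
                              "monte_carlo", degenerate)


# ---------------------------------------------------------------------------
# combination across families, LOD, burden, Bonferroni
# ---------------------------------------------------------------------------

def _poisson_binomial_pmf(probs: list[float]) -> np.ndarray:
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def cross_family_sharing_pvalue(family_probs: list[float],
                                n_shared: int) -> float:
    """P(X >= n_shared) for X ~ Poisson-binomial over per-family sharing probs.

    ``family_probs`` are the null sharing probabilities of the families
    carrying the gene; independence of transmissions across families is
    assumed.  n_shared = 0 gives p = 1.
    """
    if n_shared <= 0:
        return 1.0
    if n_shared > len(family_probs):
        raise ValueError("more sharing families than carrier families")
    pmf = _poisson_binomial_pmf(family_probs)
    return float(min(1.0, max(0.0, pmf[n_shared:].sum())))


def sharing_lod(sharing_family_probs: list[float]) -> float:
    """Sharing LOD: sum over sharing families of log10(1 / p_family)."""
    return float(sum(-math.log10(p) for p in sharing_family_probs))


def attach_sharing_statistics(results: list[GeneRecurrenceResult],
                              ped: Pedigree,
                              family_probs: dict[str, float] | None = None
                              ) -> dict[str, float]:
    """Fill p_value (sharing) and lod on recurrence results in place.

    Returns the per-family sharing probabilities used (computed once).
    """
    if family_probs is None:
        family_probs = {fam: sharing_null_probability(ped, fam).p
                        for fam in ped.families if ped.affected(fam)}
    for res in results:
        carrier_probs = [family_probs[f] for f in sorted(res.families)]
        shared_probs = [family_probs[f] for f in sorted(res.families_shared)]
        res.p_value = cross_family_sharing_pvalue(
            carrier_probs, len(res.families_shared))
        res.lod = sharing_lod(shared_probs)
    return family_probs


def burden_test(case_carriers: int, n_case: int,
                background_rate: float | None = None,
                n_background: int | None = None, *,
                background_carriers: int | None = None,
                mid_p: bool = True) -> float:
    """One-sided enrichment p for a 2x2 carrier table by exact hypergeometric.

    Case founder carriers vs background-genome carriers; ``background_rate``
    times ``n_background`` (rounded) may be given instead of a carrier count.
    Default is the mid-p tail (P(X > k) + P(X = k)/2), which is less
    conservative for small founder counts; ``mid_p=False`` gives the standard
    one-sided Fisher tail P(X >= k).
    """
    if background_carriers is None:
        if background_rate is None or n_background is None:
            raise ValueError("need background_rate+n_background or "
                             "background_carriers")
        if not 0.0 <= background_rate <= 1.0:
            raise ValueError(f"background rate {background_rate} outside [0,1]")
        background_carriers = int(round(background_rate * n_background))
    if n_case <= 0 or n_background is None or n_background <= 0:
        raise ValueError("zero-sized case or background group")
    if not 0 <= case_carriers <= n_case:
        raise ValueError("case carrier count outside [0, n_case]")

    total = n_case + n_background
    k_total = case_carriers + background_carriers
    dist = hypergeom(total, k_total, n_case)
    tail = float(dist.sf(case_carriers - 1))       # P(X >= k)
    if mid_p:
        tail -= 0.5 * float(dist.pmf(case_carriers))
    return float(min(1.0, max(0.0, tail)))


def bonferroni(p_values: list[float], alpha: float = 0.05,
               m: int | None = None) -> list[tuple[float, bool]]:
    """Bonferroni correction: adjusted p = min(1, p*m); significant iff p*m < alpha."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("need at least one test")
    return [(min(1.0, p * m), p * m < alpha) for p in p_values]


def apply_bonferroni(results: list[GeneRecurrenceResult],
                     alpha: float = 0.05) -> None:
    """Flag recurrence results in place using their p_value column."""
    ps = [r.p_value for r in results]
    if any(p is None for p in ps):
        raise ValueError("all results need a p_value before correction")
    for r, (adj, sig) in zip(results, bonferroni(ps, alpha=alpha)):
        r.p_adjusted = adj
        r.bonferroni_significant = sig
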