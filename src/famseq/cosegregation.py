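"""Within-family shared-variant extraction and inheritance-model fitting.

Model fitting follows a missing-is-unknown rule throughout: a genotype that
was never observed (member not sequenced, or call removed by QC) neither
confirms nor violates a model.  This matters for real multiplex families
where parental DNA is often unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .core_io import Cohort

__all__ = [
    "FamilyShareResult", "ModelFit", "shared_variants",
    "fit_dominant", "fit_recessive", "find_compound_het", "fit_x_linked",
    "joint_cosegregation", "JointResult", "JointCombination",
]

_X_CHROMS = {"X", "chrX", "23"}


@dataclass
class FamilyShareResult:
    """Variants carried by every affected member of one family."""

    family_id: str
    shared_idx: np.ndarray                  # indices into cohort.variants
    n_shared: int
    n_shared_lof: int
    carriers: dict[int, list[str]]          # variant index -> carrier members


@dataclass
class ModelFit:
    """Cosegregation verdict for a variant (or variant pair) in one family."""

    family_id: str
    variants: tuple                         # variant key, or pair of keys
    model: str       # dominant_full | recessive_hom | compound_het | x_linked | de_novo
    segregation: str                        # full | partial | none
    violations: list[str] = field(default_factory=list)
    phase: str | None = None                # compound hets: trans | unknown
    tolerated: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.segregation == "full" and self.violations:
            raise ValueError("full segregation cannot carry violations")


def _family_cols(cohort: Cohort, family_id: str):
    ped = cohort.pedigree
    if ped is None:
        raise ValueError("cohort has no attached pedigree")
    members = [m for m in ped.families[family_id] if m in cohort._sample_index]
    cols = {m: cohort.sample_index(m) for m in members}
    affected = [m for m in ped.affected(family_id) if m in cols]
    unaffected = [m for m in ped.unaffected(family_id) if m in cols]
    return ped, cols, affected, unaffected


def shared_variants(cohort: Cohort, family_id: str,
                    candidate_idx: np.ndarray | None = None,
                    strict: bool = True) -> FamilyShareResult:
    """Variants whose alt allele is carried by every affected member.

    In strict mode (default) a missing genotype in any affected excludes the
    site; in lenient mode missing genotypes are treated as unknown and a site
    is shared when every genotyped affected carries it and at least one does.
    """
    ped, cols, affected, _ = _family_cols(cohort, family_id)
    if len(affected) < 2:
        raise ValueError(f"family {family_id!r} has {len(affected)} genotyped "
                         "affected member(s); need >= 2")
    idx = (np.arange(cohort.n_variants) if candidate_idx is None
           else np.asarray(candidate_idx))
    aff_cols = [cols[a] for a in affected]
    gt = cohort.gt[np.ix_(idx, aff_cols)]
    if strict:
        shared = (gt > 0).all(axis=1)
    else:
        shared = ((gt > 0) | (gt < 0)).all(axis=1) & (gt > 0).any(axis=1)
    shared_idx = idx[shared]
    lof = sum(cohort.variants[i].is_lof for i in shared_idx)
    carriers = {int(i): [m for m in cols
                         if cohort.gt[i, cols[m]] > 0]
                for i in shared_idx}
    return FamilyShareResult(family_id=family_id,
                             shared_idx=shared_idx,
                             n_shared=int(shared.size and shared.sum()),
                             n_shared_lof=int(lof), carriers=carriers)


def fit_dominant(cohort: Cohort, family_id: str, vi: int,
                 max_unaffected_carriers: int = 0) -> ModelFit:
    """Fully penetrant heterozygous (dominant) model.

    Full: every genotyped affected carries >= 1 alt allele (and at least one
    affected is genotyped) while no genotyped unaffected carries any.  A
    relaxed penetrance mode tolerates up to ``max_unaffected_carriers``
    unaffected carriers, reported in ``tolerated``.
    """
    ped, cols, affected, unaffected = _family_cols(cohort, family_id)
    key = cohort.variants[vi].key
    aff_gt = {a: int(cohort.gt[vi, cols[a]]) for a in affected}
    non_carrier_aff = [a for a, g in aff_gt.items() if g == 0]
    carrier_aff = [a for a, g in aff_gt.items() if g > 0]
    unaff_carriers = sorted(u for u in unaffected
                            if cohort.gt[vi, cols[u]] > 0)

    if non_carrier_aff or not carrier_aff:
        viol = [f"affected non-carrier {a}" for a in sorted(non_carrier_aff)]
        viol += [f"unaffected carrier {u}" for u in unaff_carriers]
        return ModelFit(family_id, (key,), "dominant_full", "none",
                        violations=viol or ["no genotyped affected carrier"])
    if len(unaff_carriers) <= max_unaffected_carriers:
        return ModelFit(family_id, (key,), "dominant_full", "full",
                        tolerated=[f"unaffected carrier {u}"
                                   for u in unaff_carriers])
    return ModelFit(family_id, (key,), "dominant_full", "partial",
                    violations=[f"unaffected carrier {u}"
                                for u in unaff_carriers])


def fit_recessive(cohort: Cohort, family_id: str, vi: int) -> ModelFit:
    """Homozygous recessive model.

    Full: every genotyped affected is hom-alt (at least one genotyped), no
    genotyped unaffected is hom-alt, and every genotyped parent of an
    affected is het.  A parent genotyped hom-ref under an affected hom-alt
    child is a Mendelian inconsistency.
    """
    ped, cols, affected, unaffected = _family_cols(cohort, family_id)
    key = cohort.variants[vi].key
    violations, mendelian = [], []
    hom_aff = []
    for a in affected:
        g = int(cohort.gt[vi, cols[a]])
        if g < 0:
            continue
        if g == 2:
            hom_aff.append(a)
        else:
            violations.append(f"affected not hom-alt {a}")
        for p in ped.parents(a):
            if p is None or p not in cols:
                continue
            pg = int(cohort.gt[vi, cols[p]])
            if pg == 0 and g == 2:
                mendelian.append(f"mendelian: parent {p} hom-ref, "
                                 f"affected {a} hom-alt")
            elif pg == 2:
                violations.append(f"parent not het {p}")
    unaff_hom = sorted(u for u in unaffected if cohort.gt[vi, cols[u]] == 2)
    violations += [f"unaffected hom-alt {u}" for u in unaff_hom]
    # deduplicate while keeping order
    violations = list(dict.fromkeys(mendelian + violations))

    bad_aff = any(v.startswith("affected") for v in violations)
    if mendelian or bad_aff or not hom_aff:
        return ModelFit(family_id, (key,), "recessive_hom", "none",
                        violations=violations or ["no genotyped affected hom-alt"])
    if violations:
        return ModelFit(family_id, (key,), "recessive_hom", "partial",
                        violations=violations)
    return ModelFit(family_id, (key,), "recessive_hom", "full")


def _parent_phase(cohort: Cohort, cols, ped, member: str, vi: int, vj: int
                  ) -> str:
    """Phase evidence for one member het at both sites: trans|cis|unknown."""
    f, m = ped.parents(member)
    if f is None or m is None or f not in cols or m not in cols:
        return "unknown"
    gf = (int(cohort.gt[vi, cols[f]]), int(cohort.gt[vj, cols[f]]))
    gm = (int(cohort.gt[vi, cols[m]]), int(cohort.gt[vj, cols[m]]))
    if min(gf) < 0 or min(gm) < 0:
        return "unknown"
    if (gf[0] > 0 and gf[1] > 0) or (gm[0] > 0 and gm[1] > 0):
        return "cis"          # a parent carries both: cis-ambiguous
    if (gf[0] > 0 and gm[1] > 0) or (gm[0] > 0 and gf[1] > 0):
        return "trans"
    return "unknown"


def find_compound_het(cohort: Cohort, family_id: str, gene: str,
                      candidate_idx: np.ndarray) -> list[ModelFit]:
    """Parent-phased compound heterozygotes within one gene.

    Pairs (v1, v2) of distinct same-gene variants for which every genotyped
    affected is het at both sites.  Phase is resolved trans when one parent
    carries v1-but-not-v2 and the other v2-but-not-v1; a pair for which any
    parent of an affected carries both variants is rejected (cis-ambiguous).
    Output is symmetric in the pair and deduplicated (v1 < v2 by key).
    """
    ped, cols, affected, unaffected = _family_cols(cohort, family_id)
    idx = sorted(int(i) for i in candidate_idx
                 if cohort.variants[i].gene == gene)
    fits: list[ModelFit] = []
    for vi, vj in combinations(idx, 2):
        aff_het = []
        ok = True
        for a in affected:
            gi = int(cohort.gt[vi, cols[a]])
            gj = int(cohort.gt[vj, cols[a]])
            if gi < 0 or gj < 0:
                continue
            if gi == 1 and gj == 1:
                aff_het.append(a)
            else:
                ok = False
                break
        if not ok or not aff_het:
            continue
        phases = {a: _parent_phase(cohort, cols, ped, a, vi, vj)
                  for a in aff_het}
        if "cis" in phases.values():
            continue
        phase = "trans" if "trans" in phases.values() else "unknown"
        violations = []
        for u in unaffected:
            if (cohort.gt[vi, cols[u]] > 0 and cohort.gt[vj, cols[u]] > 0
                    and _parent_phase(cohort, cols, ped, u, vi, vj) == "trans"):
                violations.append(f"unaffected trans carrier {u}")
        keys = tuple(sorted([cohort.variants[vi].key, cohort.variants[vj].key]))
        seg = "full" if not violations else "partial"
        fits.append(ModelFit(family_id, keys, "compound_het", seg,
                             violations=violations, phase=phase))
    return fits


def fit_x_linked(cohort: Cohort, family_id: str, vi: int) -> ModelFit:
    """X-linked recessive model (hemizygous affected males)."""
    v = cohort.variants[vi]
    if v.chrom not in _X_CHROMS:
        raise ValueError(f"variant {v.key} is not on the X chromosome")
    ped, cols, affected, unaffected = _family_cols(cohort, family_id)
    violations = []
    carrier_aff = []
    for a in affected:
        g = int(cohort.gt[vi, cols[a]])
        if g < 0:
            continue
        male = ped.member(a).sex == "male"
        if male:
            if g > 0:
                carrier_aff.append(a)
            else:
                violations.append(f"affected male non-carrier {a}")
        elif g == 2:
            carrier_aff.append(a)
        else:
            violations.append(f"affected female not hom-alt {a}")
        mother = ped.parents(a)[1]
        if mother is not None and mother in cols:
            mg = int(cohort.gt[vi, cols[mother]])
            if mg >= 0 and mg != 1:
                violations.append(f"mother not het {mother}")
    for u in unaffected:
        if ped.member(u).sex == "male" and cohort.gt[vi, cols[u]] > 0:
            violations.append(f"unaffected male carrier {u}")
    violations = list(dict.fromkeys(violations))
    bad_aff = any(v_.startswith("affected") for v_ in violations)
    if bad_aff or not carrier_aff:
        return ModelFit(family_id, (v.key,), "x_linked", "none",
                        violations=violations or ["no genotyped affected carrier"])
    if violations:
        return ModelFit(family_id, (v.key,), "x_linked", "partial",
                        violations=violations)
    return ModelFit(family_id, (v.key,), "x_linked", "full")


# ---------------------------------------------------------------------------
# joint (oligogenic) cosegregation
# ---------------------------------------------------------------------------

@dataclass
class JointCombination:
    genes: tuple[str, ...]
    n_variants: int


@dataclass
class JointResult:
    family_id: str
    explained: bool
    per_affected: dict[str, list[JointCombination]]
    identical_across: bool
    flagged_unaffected: list[str]


def _gene_components(genes: list[str], graph: nx.Graph,
                     seeds: set[str]) -> list[list[str]]:
    """Connected groups of candidate genes.

    Two genes are linked when they share a direct interaction edge, or when
    both lie within one edge of (or are) a seed gene — the knowledge-layer
    route through known disease genes.
    """
    def seed_linked(g: str) -> bool:
        return g in seeds or any(graph.has_edge(g, s) for s in seeds
                                 if graph.has_node(s))

    aux = nx.Graph()
    aux.add_nodes_from(genes)
    linked = {g: seed_linked(g) for g in genes}
    for a, b in combinations(genes, 2):
        if graph.has_edge(a, b) or (linked[a] and linked[b]):
            aux.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(aux)]


def joint_cosegregation(cohort: Cohort, family_id: str,
                        candidate_idx: np.ndarray, graph: nx.Graph,
                        seed_genes: list[str], k: int = 2,
                        lenient_missing: bool = True) -> JointResult:
    """Multi-gene (oligogenic) cosegregation for one family.

    For each affected, finds connected groups of carried candidate genes with
    at least ``k`` qualifying variants; the family is explained when every
    affected has at least one such combination.  Combinations may be identical
    across affecteds or patient-specific.  Genotyped unaffecteds carrying a
    full reported combination are flagged, not excluded.

    Under ``lenient_missing`` (default) an affected's missing genotype counts
    as carried when every other genotyped affected carries the variant —
    the missing-is-unknown rule applied to candidate sharing, so that one
    unavailable or QC-dropped call does not disqualify a combination.
    """
    ped, cols, affected, unaffected = _family_cols(cohort, family_id)
    seeds = set(seed_genes)
    idx = np.asarray(sorted(int(i) for i in candidate_idx))

    aff_cols = [cols[a] for a in affected]
    aff_gt = cohort.gt[np.ix_(idx, aff_cols)] if len(idx) else \
        np.empty((0, len(aff_cols)), dtype=np.int8)
    shared_lenient = ((aff_gt > 0) | (aff_gt < 0)).all(axis=1) \
        & (aff_gt > 0).any(axis=1)
    lenient_ok = {int(i) for i in idx[shared_lenient]} if lenient_missing \
        else set()

    def member_combos(member: str) -> list[JointCombination]:
        j = cols[member]
        is_aff = member in affected
        carried = [i for i in idx if cohort.variants[i].gene
                   and (cohort.gt[i, j] > 0
                        or (is_aff and cohort.gt[i, j] < 0
                            and int(i) in lenient_ok))]
        genes = sorted({cohort.variants[i].gene for i in carried})
        out = []
        for comp in _gene_components(genes, graph, seeds):
            n = sum(1 for i in carried if cohort.variants[i].gene in comp)
            if n >= k:
                out.append(JointCombination(genes=tuple(comp), n_variants=n))
        return sorted(out, key=lambda c: c.genes)

    per_affected = {a: member_combos(a) for a in affected}
    explained = all(per_affected[a] for a in affected) and bool(affected)
    combo_sets = [frozenset(c.genes for c in v) for v in per_affected.values()]
    identical = explained and len(set(combo_sets)) == 1

    reported = sorted({c.genes for v in per_affected.values() for c in v})
    flagged = []
    for u in unaffected:
        combos_u = {c.genes for c in member_combos(u)}
        if any(g in combos_u for g in reported):
            flagged.append(u)
    return JointResult(family_id=family_id, explained=explained,
                       per_affected=per_affected, identical_across=identical,
                       flagged_unaffected=sorted(flagged))
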