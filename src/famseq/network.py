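"""Knowledge-layer linking and full three-step prioritization.

Step 1 (within-family sharing) and step 3 (cosegregation) live in
:mod:`famseq.cosegregation`; step 2's recurrence statistics in
:mod:`famseq.recurrence`.  This module links candidate genes to known disease
genes over a user-supplied interaction graph and assembles the per-family
explanation report.  Candidate explanations are ranked recurrent-gene >
monogenic full cosegregation > compound het > joint multi-gene combination —
a convention, reflecting decreasing cross-family support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_io import Cohort
from .cosegregation import (find_compound_het, fit_dominant, fit_recessive,
                            fit_x_linked, joint_cosegregation, shared_variants)
from .rare_damaging import FilterResult
from .recurrence import GeneRecurrenceResult

__all__ = ["link_candidates", "LinkResult", "prioritize",
           "Explanation", "FamilyReport"]

_X_CHROMS = {"X", "chrX", "23"}
_CLASS_ORDER = {"recurrent": 0, "dominant": 1, "recessive": 1,
                "x_linked": 1, "compound_het": 2, "joint": 3}


@dataclass
class LinkResult:
    gene: str
    linked: bool
    distance: int | None          # 0 = is a seed gene
    seeds: tuple[str, ...] = ()


def link_candidates(candidates: list[str], graph: nx.Graph,
                    seeds: list[str], max_dist: int = 1
                    ) -> dict[str, LinkResult]:
    """Shortest-path linking of candidate genes to seed (known) genes.

    A candidate is linked when its shortest path to any seed is <= max_dist;
    seed genes themselves link at distance 0.
    """
    seed_set = set(seeds)
    # multi-source BFS from the seeds present in the graph
    dist: dict[str, int] = {s: 0 for s in seed_set}
    frontier = [s for s in seed_set if graph.has_node(s)]
    d = 0
    while frontier and d < max_dist:
        d += 1
        nxt = []
        for node in frontier:
            for nb in graph.neighbors(node):
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt

    out: dict[str, LinkResult] = {}
    for gene in candidates:
        if gene in seed_set:
            out[gene] = LinkResult(gene, True, 0, (gene,))
        elif gene in dist:
            near = tuple(sorted(
                s for s in seed_set if graph.has_node(s) and graph.has_node(gene)
                and nx.has_path(graph, gene, s)
                and nx.shortest_path_length(graph, gene, s) == dist[gene]))
            out[gene] = LinkResult(gene, True, dist[gene], near)
        else:
            out[gene] = LinkResult(gene, False, None)
    return out


@dataclass
class Explanation:
    """One candidate explanation for a family's phenotype."""

    kind: str                      # recurrent | dominant | recessive |
    #                                x_linked | compound_het | joint
    genes: tuple[str, ...]
    variants: tuple = ()
    model: str | None = None
    segregation: str | None = None
    statistics: dict = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def sort_key(self):
        return (_CLASS_ORDER[self.kind], self.genes, self.variants)


@dataclass
class FamilyReport:
    family_id: str
    status: str                    # explained | unexplained
    explanations: list[Explanation]


def prioritize(cohort: Cohort, filt: FilterResult,
               graph: nx.Graph, seeds: list[str],
               recurrence: list[GeneRecurrenceResult] | None = None,
               k: int = 2) -> dict[str, FamilyReport]:
    """Assemble the ordered per-family explanation report.

    Only variants that survived the filtering cascade are referenced.  Shared
    variants are extracted in lenient (missing-is-unknown) mode so that an
    unsequenced or QC-dropped relative cannot disqualify a candidate.
    """
    ped = cohort.pedigree
    recurrence = recurrence or []
    rec_by_family: dict[str, list[GeneRecurrenceResult]] = {}
    for r in recurrence:
        for fam in r.families_shared:
            rec_by_family.setdefault(fam, []).append(r)

    reports: dict[str, FamilyReport] = {}
    for fam in ped.families:
        affected = [a for a in ped.affected(fam) if a in cohort._sample_index]
        if len(affected) < 2:
            continue
        expl: list[Explanation] = []
        share = shared_variants(cohort, fam, candidate_idx=filt.kept_idx,
                                strict=False)

        for r in sorted(rec_by_family.get(fam, []), key=lambda r: r.gene):
            stats = {k_: v for k_, v in (("p_value", r.p_value),
                                         ("lod", r.lod),
                                         ("p_burden", r.p_burden))
                     if v is not None}
            keys = tuple(sorted(
                cohort.variants[int(i)].key for i in share.shared_idx
                if cohort.variants[int(i)].gene == r.gene))
            expl.append(Explanation(kind="recurrent", genes=(r.gene,),
                                    variants=keys, statistics=stats))

        for i in share.shared_idx:
            i = int(i)
            v = cohort.variants[i]
            if v.chrom in _X_CHROMS:
                fit = fit_x_linked(cohort, fam, i)
                if fit.segregation == "full":
                    expl.append(Explanation(
                        kind="x_linked", genes=(v.gene,), variants=(v.key,),
                        model=fit.model, segregation="full"))
                continue
            for fit_fn, kind in ((fit_dominant, "dominant"),
                                 (fit_recessive, "recessive")):
                fit = fit_fn(cohort, fam, i)
                if fit.segregation == "full":
                    expl.append(Explanation(
                        kind=kind, genes=(v.gene,), variants=(v.key,),
                        model=fit.model, segregation="full"))

        genes_shared = sorted({cohort.variants[int(i)].gene
                               for i in share.shared_idx
                               if cohort.variants[int(i)].gene})
        for gene in genes_shared:
            for fit in find_compound_het(cohort, fam, gene, share.shared_idx):
                expl.append(Explanation(
                    kind="compound_het", genes=(gene,), variants=fit.variants,
                    model="compound_het", segregation=fit.segregation,
                    notes=(f"phase {fit.phase}",)
                    + tuple(fit.violations)))

        fam_cols = [cohort.sample_index(a) for a in affected]
        carried_any = filt.kept_idx[
            (cohort.gt[np.ix_(filt.kept_idx, fam_cols)] > 0).any(axis=1)]
        joint = joint_cosegregation(cohort, fam, carried_any, graph, seeds, k=k)
        if joint.explained:
            combos = sorted({c.genes for v in joint.per_affected.values()
                             for c in v})
            notes = ("identical combinations" if joint.identical_across
                     else "patient-specific combinations",)
            if joint.flagged_unaffected:
                notes += tuple(f"unaffected carrier {u}"
                               for u in joint.flagged_unaffected)
            for genes in combos:
                expl.append(Explanation(kind="joint", genes=genes,
                                        notes=notes))

        expl.sort(key=Explanation.sort_key)
        reports[fam] = FamilyReport(
            family_id=fam,
            status="explained" if expl else "unexplained",
            explanations=expl)
    return reports
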