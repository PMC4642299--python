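"""Synthetic multi-family exome cohorts with planted causal architectures.

The generator emulates the study design the pipeline targets: 8 two-patient
families of mixed kinship (siblings through fourth-degree relatives, 48
sequenced individuals), ~35x mean read depth, a rare allele-frequency
spectrum that leaves each patient with rare damaging variants in the
low-hundreds after filtering, plus a common-marker panel for IBD estimation.

Within-gene variants live on explicit founder haplotypes (two per founder) so
cis/trans phase is well defined for compound-heterozygote testing; genes are
transmitted as unrecombined blocks, genes independent of each other, and the
marker panel is unlinked.  Genotype calls are derived from simulated reads by
ratio thresholding before QC so the QC stage sees realistic borderline calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core_io import (Cohort, FrequencyResource, PredictionScores,
                      VariantKey, VariantSite, write_vcf)
from .pedigree import Pedigree, PedigreeMember

__all__ = [
    "FamilyTemplate", "Architecture", "SimulationConfig", "TruthTable",
    "PlantedVariant", "SimulatedCohort", "default_templates",
    "simulate_cohort", "mendelian_check",
]


# ---------------------------------------------------------------------------
# pedigree templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTemplate:
    """One family: (member, father, mother, sex, affected, sequenced) rows."""

    family_id: str
    members: tuple[tuple[str, str | None, str | None, str, str, bool], ...]

    def sequenced(self) -> list[str]:
        return [m[0] for m in self.members if m[5]]


def _sib_family(fam: str) -> FamilyTemplate:
    """Affected sib pair with sequenced parents and two unaffected sibs."""
    f, m = f"{fam}-I.1", f"{fam}-I.2"
    return FamilyTemplate(fam, (
        (f, None, None, "male", "no", True),
        (m, None, None, "female", "no", True),
        (f"{fam}-II.1", f, m, "male", "yes", True),
        (f"{fam}-II.2", f, m, "female", "yes", True),
        (f"{fam}-II.3", f, m, "male", "no", True),
        (f"{fam}-II.4", f, m, "female", "no", True),
    ))


def default_templates() -> list[FamilyTemplate]:
    """Eight two-patient families: 48 sequenced individuals, 16 affected.

    fam1 and fam5 are affected parent-offspring pairs (fam1's top generation
    unsequenced, fam5's affected parent a sequenced founder), fam7 an affected
    fourth-degree pair (first cousins once removed), the rest affected sib
    pairs.
    """
    fam1 = FamilyTemplate("fam1", (
        ("fam1-I.1", None, None, "male", "no", False),
        ("fam1-I.2", None, None, "female", "no", False),
        ("fam1-II.1", None, None, "female", "no", True),
        ("fam1-II.2", "fam1-I.1", "fam1-I.2", "male", "yes", True),
        ("fam1-III.3", "fam1-II.2", "fam1-II.1", "male", "yes", True),
        ("fam1-III.4", "fam1-II.2", "fam1-II.1", "female", "no", True),
    ))
    fam5 = FamilyTemplate("fam5", (
        ("fam5-I.1", None, None, "male", "no", True),
        ("fam5-I.2", None, None, "female", "yes", True),
        ("fam5-II.1", "fam5-I.1", "fam5-I.2", "female", "yes", True),
        ("fam5-II.2", "fam5-I.1", "fam5-I.2", "male", "no", True),
    ))
    fam7 = FamilyTemplate("fam7", (
        ("fam7-I.1", None, None, "male", "no", True),
        ("fam7-I.2", None, None, "female", "no", True),
        ("fam7-II.1", "fam7-I.1", "fam7-I.2", "male", "no", True),
        ("fam7-II.2", "fam7-I.1", "fam7-I.2", "female", "no", True),
        ("fam7-II.3", None, None, "female", "no", True),
        ("fam7-II.4", None, None, "male", "no", True),
        ("fam7-III.1", "fam7-II.1", "fam7-II.3", "male", "yes", True),
        ("fam7-III.2", "fam7-II.4", "fam7-II.2", "female", "no", True),
        ("fam7-III.3", None, None, "male", "no", True),
        ("fam7-IV.1", "fam7-III.3", "fam7-III.2", "male", "yes", True),
    ))
    return [fam1, _sib_family("fam2"), _sib_family("fam3"),
            _sib_family("fam4"), fam5, _sib_family("fam6"), fam7,
            _sib_family("fam8")]


def templates_to_pedigree(templates: list[FamilyTemplate]) -> Pedigree:
    members = []
    for t in templates:
        for iid, fa, mo, sex, aff, _seq in t.members:
            members.append(PedigreeMember(t.family_id, iid, fa, mo, sex, aff))
    return Pedigree(members)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """One planted causal architecture."""

    family_id: str
    model: str                  # dominant | recessive | compound_het | digenic
    genes: tuple[str, ...]      # one gene (two for digenic)
    consequence: str = "missense"


@dataclass
class SimulationConfig:
    """Cohort generator settings; defaults are the target study conditions.

    The variant panel size is calibrated so that, with the rare log-uniform
    AF spectrum in [1e-5, 5e-3] and the consequence/predictor mix below, each
    patient retains rare damaging variants in the ~130-210 range after the
    filtering cascade.  Depth is negative-binomial with mean ~35 reads.
    """

    seed: int
    templates: list[FamilyTemplate] = field(default_factory=default_templates)
    n_genes: int = 17_000
    variants_per_gene_mean: float = 20.0
    rare_af_range: tuple[float, float] = (1e-5, 5e-3)
    common_fraction: float = 0.05
    common_af_range: tuple[float, float] = (0.05, 0.30)
    indel_fraction: float = 0.10
    transition_fraction: float = 0.76
    lof_fraction: float = 0.08
    missense_fraction: float = 0.62
    synonymous_fraction: float = 0.25
    missense_damaging_fraction: float = 0.35
    predictor_unknown_rate: float = 0.05
    predictor_d_given_damaging: float = 0.90
    predictor_d_given_benign: float = 0.15
    depth_mean: float = 35.0
    depth_dispersion: float = 8.0       # negative-binomial size parameter
    error_rate: float = 0.005
    call_het_ratio: float = 0.20        # alt ratio above which a het is called
    call_hom_ratio: float = 0.80        # alt ratio above which hom-alt is called
    known_sites_rate: float = 0.95
    db_presence_rare: float = 0.50
    db_presence_common: float = 0.98
    db_names: tuple[str, ...] = ("dbsnp_like", "thousand_genomes_like",
                                 "esp_like")
    marker_panel_size: int = 5000
    marker_maf_range: tuple[float, float] = (0.05, 0.50)
    n_background_edges: int = 200
    architectures: list[Architecture] = field(default_factory=list)

    def scaled(self, factor: float) -> "SimulationConfig":
        """A copy with the gene panel scaled down (problem-size control)."""
        return replace(self, n_genes=max(1, int(self.n_genes * factor)))


@dataclass
class PlantedVariant:
    key: VariantKey
    family_id: str
    model: str
    gene: str
    expected_carriers: dict[str, int]       # sequenced member -> true dosage


@dataclass
class TruthTable:
    planted: list[PlantedVariant]

    def for_family(self, family_id: str) -> list[PlantedVariant]:
        return [p for p in self.planted if p.family_id == family_id]


@dataclass
class SimulatedCohort:
    """Everything the downstream pipeline consumes, plus the truth."""

    cohort: Cohort                      # called genotypes with read support
    truth_gt: np.ndarray                # true dosages (variants x samples)
    resources: list[FrequencyResource]
    scores: PredictionScores
    annotation: dict[VariantKey, tuple[str, str]]
    known_sites: set[VariantKey]
    graph: nx.Graph
    truth: TruthTable
    marker_genotypes: np.ndarray        # markers x samples true dosage
    marker_afs: np.ndarray
    marker_cohort: Cohort | None        # marker records with read-backed calls
    config: SimulationConfig

    def write(self, outdir) -> dict[str, str]:
        return write_cohort(self, outdir)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_alleles(rng, n, indel_fraction, transition_fraction):
    ref = _BASES[rng.integers(0, 4, size=n)]
    alt = np.empty(n, dtype=object)
    is_indel = rng.random(n) < indel_fraction
    is_ins = rng.random(n) < 0.5
    is_ti = rng.random(n) < transition_fraction
    tv_pick = rng.integers(0, 2, size=n)
    ref = list(ref)
    for i in range(n):
        r = ref[i]
        if is_indel[i]:
            if is_ins[i]:
                alt[i] = r + "A"                      # insertion
            else:
                ref[i], alt[i] = r + "A", r           # deletion
        elif is_ti[i]:
            alt[i] = _TRANSITION[r]
        else:
            choices = [b for b in "ACGT" if b != r and b != _TRANSITION[r]]
            alt[i] = choices[tv_pick[i]]
    return ref, list(alt)


def _drop_haplotypes(ped: Pedigree, gene_index: np.ndarray, n_genes: int,
                     founder_haps: dict[str, np.ndarray], rng
                     ) -> dict[str, np.ndarray]:
    """Transmit founder haplotypes through every family, gene-block-wise."""
    haps: dict[str, np.ndarray] = dict(founder_haps)
    M = len(gene_index)
    for fam in ped.families:
        for iid in ped.topological(fam):
            if ped.member(iid).is_founder:
                continue
            h = np.zeros((M, 2), dtype=np.int8)
            for slot, parent in enumerate(ped.parents(iid)):
                if parent is None:
                    continue
                choice = rng.integers(0, 2, size=n_genes)[gene_index]
                h[:, slot] = haps[parent][np.arange(M), choice]
            haps[iid] = h
    return haps


def _simulate_reads(truth_gt, cfg: SimulationConfig, rng):
    """Depths, alt counts and ratio-threshold genotype calls."""
    shape = truth_gt.shape
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    dp = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=shape)
    p_alt = np.select([truth_gt == 0, truth_gt == 1],
                      [cfg.error_rate, 0.5], default=1.0 - cfg.error_rate)
    ad = rng.binomial(dp, p_alt)
    ratio = np.divide(ad, dp, out=np.zeros_like(ad, dtype=float),
                      where=dp > 0)
    called = np.select(
        [dp == 0, ratio > cfg.call_hom_ratio, ratio > cfg.call_het_ratio],
        [-1, 2, 1], default=0).astype(np.int8)
    return dp.astype(np.int32), ad.astype(np.int32), called


def _plant(cfg: SimulationConfig, ped: Pedigree, samples: list[str],
           next_chrom_slot: int) -> tuple[list[dict], list[PlantedVariant],
                                          list[tuple[str, str]]]:
    """Resolve planted architectures into explicit haplotype assignments.

    Returns per-variant specs ({gene, chrom, pos, consequence, hap carriers}),
    truth rows and extra graph edges.
    """
    specs: list[dict] = []
    truth_rows: list[PlantedVariant] = []
    edges: list[tuple[str, str]] = []
    seq = set(samples)

    def fail(fam, why):
        raise ValueError(f"unsatisfiable architecture in family {fam!r}: {why}")

    def sib_setup(fam):
        aff = ped.affected(fam)
        if len(aff) < 2:
            fail(fam, "needs >= 2 affected members")
        parents = {ped.parents(a) for a in aff}
        if len(parents) != 1 or None in next(iter(parents)):
            fail(fam, "affected members are not full siblings with both "
                      "parents in the pedigree")
        father, mother = next(iter(parents))
        return aff, father, mother

    def ancestors_of(iid):
        out, stack = set(), [iid]
        while stack:
            for p_ in ped.parents(stack.pop()):
                if p_ is not None and p_ not in out:
                    out.add(p_)
                    stack.append(p_)
        return out

    def dominant_chain(fam):
        aff = ped.affected(fam)
        if len(aff) < 2:
            fail(fam, "needs >= 2 affected members")
        # order by depth; require a direct ancestor chain through affecteds
        aff = sorted(aff, key=ped.depth)
        chain = [aff[0]]
        for nxt in aff[1:]:
            if chain[-1] not in ancestors_of(nxt):
                fail(fam, "affected members are not in one ancestor line; "
                          "a fully penetrant dominant allele cannot avoid "
                          "unaffected carriers")
            path = [nxt]
            cur = nxt
            while cur != chain[-1]:
                fa, mo = ped.parents(cur)
                if fa is not None and (fa == chain[-1]
                                       or chain[-1] in ancestors_of(fa)):
                    cur = fa
                elif mo is not None and (mo == chain[-1]
                                         or chain[-1] in ancestors_of(mo)):
                    cur = mo
                else:  # pragma: no cover - guarded by the ancestor test above
                    fail(fam, "broken ancestor path")
                path.append(cur)
            chain.extend(reversed(path[:-1]))
        # extend above the top affected to a founder, avoiding sequenced
        # unaffected carriers (they would break full penetrance)
        top = chain[0]
        up = []
        cur = top
        while not ped.member(cur).is_founder:
            fa, mo = ped.parents(cur)
            pick = None
            for cand in (fa, mo):
                if cand is not None and cand not in seq:
                    pick = cand
                    break
            if pick is None:
                fail(fam, "every ancestor of the affected line is a sequenced "
                          "unaffected; planted dominant would not be fully "
                          "penetrant")
            up.append(pick)
            cur = pick
        full_chain = list(reversed(up)) + chain
        for m in full_chain:
            if m in seq and ped.member(m).affected == "no":
                fail(fam, f"forced carrier {m} is a sequenced unaffected")
        return full_chain

    def hap_slot(child, parent):
        fa, mo = ped.parents(child)
        return 0 if parent == fa else 1

    slot = next_chrom_slot
    for arch in cfg.architectures:
        fam = arch.family_id
        if fam not in ped.families:
            fail(fam, "unknown family")
        chrom = str(1 + slot % 22)
        base = 200_000_000 + 1000 * slot
        slot += 1
        if arch.model == "dominant":
            chain = dominant_chain(fam)
            carriers: dict[str, list[int]] = {}
            for j, m in enumerate(chain):
                if j == 0:
                    carriers[m] = [0]
                else:
                    carriers[m] = [hap_slot(m, chain[j - 1])]
            specs.append(dict(gene=arch.genes[0], chrom=chrom, pos=base,
                              consequence=arch.consequence, carriers=carriers))
            truth_rows.append(PlantedVariant(
                key=(chrom, base, "G", "T"), family_id=fam, model="dominant",
                gene=arch.genes[0],
                expected_carriers={m: 1 for m in chain if m in seq}))
        elif arch.model == "recessive":
            aff, father, mother = sib_setup(fam)
            sibs = [s for s in ped.families[fam]
                    if ped.parents(s) == (father, mother) and s not in aff]
            carriers = {father: [0], mother: [0]}
            for a in aff:
                carriers[a] = [0, 1]
            if sibs:                       # one unaffected sib rides along het
                carriers[sibs[0]] = [0]
            specs.append(dict(gene=arch.genes[0], chrom=chrom, pos=base,
                              consequence=arch.consequence, carriers=carriers))
            expected = {m: len(h) for m, h in carriers.items() if m in seq}
            truth_rows.append(PlantedVariant(
                key=(chrom, base, "G", "T"), family_id=fam, model="recessive",
                gene=arch.genes[0], expected_carriers=expected))
        elif arch.model == "compound_het":
            aff, father, mother = sib_setup(fam)
            c1 = {father: [0]}
            c2 = {mother: [0]}
            for a in aff:
                c1[a] = [0]                # paternal slot
                c2[a] = [1]                # maternal slot
            for pos_off, cmap in ((0, c1), (10, c2)):
                specs.append(dict(gene=arch.genes[0], chrom=chrom,
                                  pos=base + pos_off,
                                  consequence=arch.consequence, carriers=cmap))
                truth_rows.append(PlantedVariant(
                    key=(chrom, base + pos_off, "G", "T"), family_id=fam,
                    model="compound_het", gene=arch.genes[0],
                    expected_carriers={m: len(h) for m, h in cmap.items()
                                       if m in seq}))
        elif arch.model == "digenic":
            if len(arch.genes) != 2:
                fail(fam, "digenic architecture needs a gene pair")
            aff, father, mother = sib_setup(fam)
            gene_a, gene_b = arch.genes
            ca = {father: [0]}
            cb = {mother: [0]}
            for a in aff:
                ca[a] = [0]
                cb[a] = [1]
            specs.append(dict(gene=gene_a, chrom=chrom, pos=base,
                              consequence=arch.consequence, carriers=ca))
            specs.append(dict(gene=gene_b, chrom=chrom, pos=base + 10,
                              consequence=arch.consequence, carriers=cb))
            for g, cmap, off in ((gene_a, ca, 0), (gene_b, cb, 10)):
                truth_rows.append(PlantedVariant(
                    key=(chrom, base + off, "G", "T"), family_id=fam,
                    model="digenic", gene=g,
                    expected_carriers={m: len(h) for m, h in cmap.items()
                                       if m in seq}))
            edges.append((gene_a, gene_b))
        else:
            fail(fam, f"unknown model {arch.model!r}")
    return specs, truth_rows, edges


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort: genotypes, reads, resources, truth, markers."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ped = templates_to_pedigree(cfg.templates)
    samples = [iid for t in cfg.templates for iid in t.sequenced()]

    # ---- background variant panel -----------------------------------------
    counts = rng.poisson(cfg.variants_per_gene_mean, size=cfg.n_genes)
    counts = np.maximum(counts, 0)
    gene_index = np.repeat(np.arange(cfg.n_genes), counts)
    M = len(gene_index)
    gene_names = np.array([f"GENE{g:05d}" for g in range(cfg.n_genes)])
    gene_chrom = np.array([str(1 + g % 22) for g in range(cfg.n_genes)])

    # positions: per-gene 100 kb blocks along each chromosome
    blocks_on_chrom = np.zeros(cfg.n_genes, dtype=np.int64)
    per_chrom_counter: dict[str, int] = {}
    for g in range(cfg.n_genes):
        c = gene_chrom[g]
        blocks_on_chrom[g] = per_chrom_counter.get(c, 0)
        per_chrom_counter[c] = blocks_on_chrom[g] + 1
    offset_in_gene = np.concatenate([np.arange(c) for c in counts]) \
        if M else np.empty(0, dtype=int)
    pos = (blocks_on_chrom[gene_index] * 100_000 + 1
           + offset_in_gene * 50).astype(np.int64)

    is_common = rng.random(M) < cfg.common_fraction
    lo, hi = cfg.rare_af_range
    af = np.exp(rng.uniform(np.log(lo), np.log(hi), size=M))
    af[is_common] = rng.uniform(*cfg.common_af_range, size=int(is_common.sum()))

    ref, alt = _draw_alleles(rng, M, cfg.indel_fraction,
                             cfg.transition_fraction)
    p_other = max(0.0, 1.0 - cfg.lof_fraction - cfg.missense_fraction
                  - cfg.synonymous_fraction)
    consequence = rng.choice(
        np.array(["LOF", "missense", "synonymous", "other"]), size=M,
        p=[cfg.lof_fraction, cfg.missense_fraction, cfg.synonymous_fraction,
           p_other])

    # ---- founder haplotypes and gene dropping -----------------------------
    founder_haps = {}
    for fam in ped.families:
        for iid in ped.founders(fam):
            founder_haps[iid] = (rng.random((M, 2)) < af[:, None]).astype(np.int8)
    haps = _drop_haplotypes(ped, gene_index, cfg.n_genes, founder_haps, rng)

    # ---- planted architectures --------------------------------------------
    specs, truth_rows, extra_edges = _plant(cfg, ped, samples, cfg.n_genes)
    n_planted = len(specs)
    if n_planted:
        for iid in haps:
            haps[iid] = np.vstack([haps[iid],
                                   np.zeros((n_planted, 2), dtype=np.int8)])
        for row, spec in enumerate(specs):
            for member, slots in spec["carriers"].items():
                for s in slots:
                    haps[member][M + row, s] = 1

    variants: list[VariantSite] = []
    for i in range(M):
        variants.append(VariantSite(
            chrom=str(gene_chrom[gene_index[i]]), pos=int(pos[i]),
            ref=ref[i], alt=alt[i], gene=str(gene_names[gene_index[i]]),
            consequence=str(consequence[i])))
    for spec in specs:
        variants.append(VariantSite(
            chrom=spec["chrom"], pos=spec["pos"], ref="G", alt="T",
            gene=spec["gene"], consequence=spec["consequence"]))
    M_all = M + n_planted

    truth_gt = np.zeros((M_all, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        truth_gt[:, j] = haps[s].sum(axis=1)

    # ---- reads and genotype calls -----------------------------------------
    dp, ad, called = _simulate_reads(truth_gt, cfg, rng)

    # ---- frequency resources, scores, annotation, known sites -------------
    af_all = np.concatenate([af, np.full(n_planted, cfg.rare_af_range[0])])
    is_common_all = np.concatenate([is_common, np.zeros(n_planted, dtype=bool)])
    presence_p = np.where(is_common_all, cfg.db_presence_common,
                          cfg.db_presence_rare)
    resources = []
    for name in cfg.db_names:
        present = rng.random(M_all) < presence_p
        present[M:] = False                      # planted variants are novel
        maf = {variants[i].key: float(min(af_all[i], 1.0 - af_all[i]))
               for i in np.flatnonzero(present)}
        resources.append(FrequencyResource(name=name, maf=maf))

    is_missense = np.array([v.consequence == "missense" for v in variants])
    latent_damaging = rng.random(M_all) < cfg.missense_damaging_fraction
    latent_damaging[M:] = True                   # planted variants are damaging
    from .core_io import PREDICTOR_NAMES
    mis_idx = np.flatnonzero(is_missense)
    n_pred = len(PREDICTOR_NAMES)
    d_p = np.where(latent_damaging[mis_idx], cfg.predictor_d_given_damaging,
                   cfg.predictor_d_given_benign)
    unknown_m = rng.random((len(mis_idx), n_pred)) < cfg.predictor_unknown_rate
    damaging_m = rng.random((len(mis_idx), n_pred)) < d_p[:, None]
    planted_m = mis_idx >= M                     # planted: all-damaging calls
    unknown_m[planted_m] = False
    damaging_m[planted_m] = True
    calls: dict[VariantKey, dict[str, str]] = {}
    for r, i in enumerate(mis_idx):
        calls[variants[i].key] = {
            pred: ("unknown" if unknown_m[r, c]
                   else "damaging" if damaging_m[r, c] else "benign")
            for c, pred in enumerate(PREDICTOR_NAMES)}
    scores = PredictionScores(calls=calls)

    annotation = {v.key: (v.gene, v.consequence) for v in variants}
    known_mask = rng.random(M_all) < cfg.known_sites_rate
    known_mask[M:] = False
    known_sites = {variants[i].key for i in np.flatnonzero(known_mask)}

    # ---- interaction graph ------------------------------------------------
    graph = nx.Graph()
    if cfg.n_genes >= 2 and cfg.n_background_edges:
        a = rng.integers(0, cfg.n_genes, size=cfg.n_background_edges)
        b = rng.integers(0, cfg.n_genes, size=cfg.n_background_edges)
        for x, y in zip(a, b):
            if x != y:
                graph.add_edge(str(gene_names[x]), str(gene_names[y]),
                               source="simulated")
    for x, y in extra_edges:
        graph.add_edge(x, y, source="simulated")

    # ---- common marker panel (unlinked) -----------------------------------
    n_mark = cfg.marker_panel_size
    marker_afs = rng.uniform(*cfg.marker_maf_range, size=n_mark)
    marker_gt = np.zeros((n_mark, len(samples)), dtype=np.int8)
    if n_mark:
        mhaps: dict[str, np.ndarray] = {}
        for fam in ped.families:
            for iid in ped.founders(fam):
                mhaps[iid] = (rng.random((n_mark, 2))
                              < marker_afs[:, None]).astype(np.int8)
            for iid in ped.topological(fam):
                if ped.member(iid).is_founder:
                    continue
                h = np.zeros((n_mark, 2), dtype=np.int8)
                for slot, parent in enumerate(ped.parents(iid)):
                    if parent is None:
                        continue
                    choice = rng.integers(0, 2, size=n_mark)
                    h[:, slot] = mhaps[parent][np.arange(n_mark), choice]
                mhaps[iid] = h
        for j, s in enumerate(samples):
            marker_gt[:, j] = mhaps[s].sum(axis=1)

    # marker panel as proper (common, intergenic) SNV records: these are the
    # sites the kinship stage extracts back out of the VCF
    marker_cohort = None
    if n_mark:
        m_ref, m_alt = _draw_alleles(rng, n_mark, 0.0,
                                     cfg.transition_fraction)
        marker_sites = [VariantSite(chrom=str(1 + i % 22),
                                    pos=300_000_000 + 100 * (i // 22),
                                    ref=m_ref[i], alt=m_alt[i],
                                    gene="", consequence="other")
                        for i in range(n_mark)]
        m_dp, m_ad, m_called = _simulate_reads(marker_gt, cfg, rng)
        marker_cohort = Cohort(marker_sites, samples, m_called, m_dp, m_ad,
                               pedigree=ped)
        known_sites |= {v.key for v in marker_sites}     # common, hence known
        annotation.update({v.key: ("", "other") for v in marker_sites})

    cohort = Cohort(variants, samples, called, dp, ad, pedigree=ped)
    return SimulatedCohort(
        cohort=cohort, truth_gt=truth_gt, resources=resources, scores=scores,
        annotation=annotation, known_sites=known_sites, graph=graph,
        truth=TruthTable(planted=truth_rows), marker_genotypes=marker_gt,
        marker_afs=marker_afs, marker_cohort=marker_cohort, config=cfg)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def mendelian_check(cohort: Cohort) -> int:
    """Count genotype configurations impossible under Mendelian transmission.

    Checked over every (father, mother, child) trio resolvable from the
    pedigree with all three genotyped at a site.
    """
    ped = cohort.pedigree
    if ped is None:
        raise ValueError("cohort has no attached pedigree")
    total = 0
    gt = cohort.gt
    for fam in ped.families:
        for iid in ped.families[fam]:
            fa, mo = ped.parents(iid)
            if fa is None or mo is None:
                continue
            if not all(x in cohort._sample_index for x in (iid, fa, mo)):
                continue
            c = gt[:, cohort.sample_index(iid)]
            f = gt[:, cohort.sample_index(fa)]
            m = gt[:, cohort.sample_index(mo)]
            ok = (c >= 0) & (f >= 0) & (m >= 0)
            cmin = (f == 2).astype(np.int8) + (m == 2).astype(np.int8)
            cmax = (f >= 1).astype(np.int8) + (m >= 1).astype(np.int8)
            total += int((ok & ((c < cmin) | (c > cmax))).sum())
    return total


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def write_cohort(sim: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the simulated cohort as standard text inputs (VCF/PED/TSV)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    out_cohort = sim.cohort
    if sim.marker_cohort is not None:
        out_cohort = Cohort(
            sim.cohort.variants + sim.marker_cohort.variants,
            sim.cohort.samples,
            np.vstack([sim.cohort.gt, sim.marker_cohort.gt]),
            np.vstack([sim.cohort.dp, sim.marker_cohort.dp]),
            np.vstack([sim.cohort.ad, sim.marker_cohort.ad]),
            pedigree=sim.cohort.pedigree)
    write_vcf(out_cohort, p("cohort.vcf"))
    with open(p("cohort.ped"), "w") as fh:
        fh.write(sim.cohort.pedigree.to_ped_text())
    for res in sim.resources:
        with open(p(f"freq_{res.name}.tsv"), "w") as fh:
            fh.write("chrom\tpos\tref\talt\tmaf\n")
            for (c, pos, r, a), maf in sorted(res.maf.items()):
                fh.write(f"{c}\t{pos}\t{r}\t{a}\t{maf:.8g}\n")
    from .core_io import PREDICTOR_NAMES
    with open(p("scores.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(PREDICTOR_NAMES) + "\n")
        code = {"damaging": "D", "benign": "B", "unknown": "U"}
        for key in sorted(sim.scores.calls):
            row = sim.scores.calls[key]
            fh.write("\t".join([key[0], str(key[1]), key[2], key[3]]
                               + [code[row.get(n, "unknown")]
                                  for n in PREDICTOR_NAMES]) + "\n")
    with open(p("annotation.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tconsequence\n")
        for key, (gene, csq) in sorted(sim.annotation.items()):
            fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{gene}\t{csq}\n")
    with open(p("known_sites.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(sim.known_sites):
            fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\n")
    with open(p("edges.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, data in sorted(sim.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('source', '')}\n")
    with open(p("truth.json"), "w") as fh:
        json.dump([{
            "key": list(pv.key), "family_id": pv.family_id, "model": pv.model,
            "gene": pv.gene, "expected_carriers": pv.expected_carriers,
        } for pv in sim.truth.planted], fh, indent=1, sort_keys=True)
    return paths
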