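"""Domain types and readers/writers for VCF, PED, TSV resources and fixtures.

Coordinates are 1-based inclusive (VCF convention).  A variant is identified
by its key ``(chrom, pos, ref, alt)``; multiallelic records are decomposed on
read so every :class:`VariantSite` carries exactly one alt allele.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _resources
from typing import Iterable

import networkx as nx
import numpy as np

from .pedigree import Pedigree, read_ped  # noqa: F401  (re-exported)

log = logging.getLogger("famseq")

VariantKey = tuple[str, int, str, str]

#: site metrics recognised by the hard filters
SITE_METRIC_NAMES = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum",
                     "ReadPosRankSum", "InbreedingCoeff")

PREDICTOR_NAMES = ("Polyphen2", "Sift", "MutationTaster", "PhyloP",
                   "LikelihoodRatio")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantSite:
    """One alt allele at one locus, with site metrics and annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"    # LOF | missense | synonymous | other
    site_metrics: dict[str, float] = field(default_factory=dict)
    filter_label: str = "PASS"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_lof(self) -> bool:
        return self.consequence == "LOF"


@dataclass
class GenotypeCall:
    """Per-sample allele pair with read-depth support.

    ``alleles`` is an ordered pair over {"ref", "alt", "missing"}; a missing
    genotype has both alleles missing.  Depths are None when the VCF carried
    no depth fields.
    """

    sample_id: str
    alleles: tuple[str, str]
    depth_total: int | None = None
    depth_alt: int | None = None

    def __post_init__(self):
        if ("missing" in self.alleles
                and self.alleles != ("missing", "missing")):
            raise ValueError("half-missing genotypes are normalized to missing")
        if (self.depth_total is not None and self.depth_alt is not None
                and not 0 <= self.depth_alt <= self.depth_total):
            raise ValueError(
                f"depth_alt {self.depth_alt} outside [0, {self.depth_total}]")

    @property
    def dosage(self) -> int | None:
        """Alt-allele count, or None when missing."""
        if self.alleles == ("missing", "missing"):
            return None
        return sum(a == "alt" for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return self.dosage == 1

    @property
    def is_missing(self) -> bool:
        return self.alleles == ("missing", "missing")


_ALLELE_FROM_DOSAGE = {0: ("ref", "ref"), 1: ("ref", "alt"), 2: ("alt", "alt")}


class Cohort:
    """A call set: variants x samples with dosage and depth matrices.

    ``gt`` holds alt dosages (int8; -1 = missing), ``dp``/``ad`` total and
    alt-supporting read depths (int32; -1 = unknown).
    """

    def __init__(self, variants: list[VariantSite], samples: list[str],
                 gt: np.ndarray, dp: np.ndarray | None = None,
                 ad: np.ndarray | None = None,
                 pedigree: Pedigree | None = None):
        n_v, n_s = len(variants), len(samples)
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (n_v, n_s):
            raise ValueError(f"gt shape {gt.shape} != ({n_v}, {n_s})")
        self.variants = variants
        self.samples = list(samples)
        self.gt = gt
        self.dp = (np.full((n_v, n_s), -1, dtype=np.int32) if dp is None
                   else np.asarray(dp, dtype=np.int32))
        self.ad = (np.full((n_v, n_s), -1, dtype=np.int32) if ad is None
                   else np.asarray(ad, dtype=np.int32))
        self.pedigree = pedigree
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        keys = [v.key for v in variants]
        self._key_index = {k: i for i, k in enumerate(keys)}
        if len(self._key_index) != n_v:
            raise ValueError("variant keys are not unique within the call set")

    # -- indexing -----------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_index(self, key: VariantKey) -> int:
        return self._key_index[key]

    def genotype_call(self, vi: int, sample_id: str) -> GenotypeCall:
        j = self._sample_index[sample_id]
        d = int(self.gt[vi, j])
        alleles = ("missing", "missing") if d < 0 else _ALLELE_FROM_DOSAGE[d]
        dp = int(self.dp[vi, j])
        ad = int(self.ad[vi, j])
        return GenotypeCall(sample_id, alleles,
                            depth_total=None if dp < 0 else dp,
                            depth_alt=None if ad < 0 else ad)

    def records(self) -> Iterable[tuple[VariantSite, list[GenotypeCall]]]:
        for i, v in enumerate(self.variants):
            yield v, [self.genotype_call(i, s) for s in self.samples]

    # -- convenience masks --------------------------------------------------

    def carrier_mask(self) -> np.ndarray:
        """Boolean (variants x samples): genotyped and carrying >= 1 alt."""
        return self.gt > 0

    def subset_variants(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort([self.variants[i] for i in idx], self.samples,
                      self.gt[idx], self.dp[idx], self.ad[idx], self.pedigree)


# ---------------------------------------------------------------------------
# frequency / score / annotation / graph resources
# ---------------------------------------------------------------------------

@dataclass
class FrequencyResource:
    """Per-database variant -> minor allele frequency map.

    An absent key means the variant was not observed in this resource.
    """

    name: str
    maf: dict[VariantKey, float]

    def __post_init__(self):
        for k, v in self.maf.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"MAF {v} for {k} outside [0, 1]")

    def get(self, key: VariantKey) -> float | None:
        return self.maf.get(key)


@dataclass
class PredictionScores:
    """Per-variant categorical damaging calls for the five predictors.

    Calls are ``damaging`` / ``benign`` / ``unknown``; unknown predictors do
    not vote in the consensus.
    """

    calls: dict[VariantKey, dict[str, str]]

    def get(self, key: VariantKey) -> dict[str, str]:
        return self.calls.get(key, {})


@dataclass
class CohortFixture:
    """The in-package encodings of the study's printed tables.

    ``patients`` mirrors the per-patient characteristics table (16 patients,
    8 families, with the RET enhancer rs2435357 genotype); ``recurrent_genes``
    the recurrent-gene table (9 genes with sharing counts, p and LOD);
    ``fat3_variants`` the FAT3 variant table (6 variants, per-database MAFs
    and predictor calls).
    """

    patients: list[dict]
    recurrent_genes: list[dict]
    fat3_variants: list[dict]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, ped: Pedigree | None = None, decompose: bool = True) -> Cohort:
    """Read a VCF 4.x into a :class:`Cohort`.

    Multiallelic records are decomposed into one :class:`VariantSite` per alt
    allele; the per-alt genotype dosage is the count of that alt allele in the
    sample's genotype.  When ``ped`` is given, VCF samples absent from the
    pedigree are dropped with a logged warning (control cohorts may ride along
    in the same VCF).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    keep = list(range(len(samples)))
    if ped is not None:
        keep = [j for j, s in enumerate(samples) if s in ped.members]
        dropped = [s for s in samples if s not in ped.members]
        if dropped:
            log.warning("dropping %d VCF sample(s) not in pedigree: %s",
                        len(dropped), ", ".join(dropped))
        samples = [samples[j] for j in keep]

    variants: list[VariantSite] = []
    gt_rows, dp_rows, ad_rows = [], [], []
    warned_depth = False
    for rec in vcf:
        alts = rec.ALT or []
        gts = rec.genotypes  # [[a1, a2, phased], ...] (or haploid [a1, phased])
        try:
            ad_arr = rec.format("AD")
        except KeyError:
            ad_arr = None
        try:
            dp_arr = rec.format("DP")
        except KeyError:
            dp_arr = None
        if dp_arr is None and ad_arr is not None:
            dp_arr = np.clip(ad_arr, 0, None).sum(axis=1, keepdims=True)
        if (dp_arr is None or ad_arr is None) and not warned_depth:
            log.warning("VCF %s lacks AD/DP depth fields; depths set unknown",
                        path)
            warned_depth = True

        metrics = {name: float(rec.INFO[name]) for name in SITE_METRIC_NAMES
                   if rec.INFO.get(name) is not None}
        gene = rec.INFO.get("GENE") or ""
        csq = rec.INFO.get("CSQCLASS") or "other"
        flabel = rec.FILTER or "PASS"

        alt_iter = list(enumerate(alts, start=1))
        if not decompose:
            alt_iter = alt_iter[:1]
        for k, alt in alt_iter:
            variants.append(VariantSite(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                gene=gene, consequence=csq, site_metrics=metrics,
                filter_label=flabel))
            row_gt = np.empty(len(keep), dtype=np.int8)
            row_dp = np.full(len(keep), -1, dtype=np.int32)
            row_ad = np.full(len(keep), -1, dtype=np.int32)
            for out_j, j in enumerate(keep):
                alleles = gts[j][:-1]  # strip phased flag
                if all(a < 0 for a in alleles):
                    row_gt[out_j] = -1
                else:
                    row_gt[out_j] = sum(a == k for a in alleles)
                if dp_arr is not None:
                    d = int(dp_arr[j][0] if np.ndim(dp_arr) > 1 else dp_arr[j])
                    row_dp[out_j] = max(d, 0) if d >= 0 else -1
                if ad_arr is not None and ad_arr.shape[1] > k:
                    a = int(ad_arr[j][k])
                    row_ad[out_j] = a if a >= 0 else -1
            gt_rows.append(row_gt)
            dp_rows.append(row_dp)
            ad_rows.append(row_ad)
    vcf.close()

    n = len(variants)
    shape = (n, len(samples))
    gt = np.vstack(gt_rows) if n else np.empty(shape, dtype=np.int8)
    dp = np.vstack(dp_rows) if n else np.full(shape, -1, dtype=np.int32)
    ad = np.vstack(ad_rows) if n else np.full(shape, -1, dtype=np.int32)
    return Cohort(variants, samples, gt, dp, ad, pedigree=ped)


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: Cohort, path) -> None:
    """Write a cohort as an uncompressed biallelic VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: dict[str, None] = {}
        for v in cohort.variants:
            seen.setdefault(v.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQCLASS,Number=1,Type=String,'
                 'Description="Consequence class">\n')
        for name in SITE_METRIC_NAMES:
            fh.write(f'##INFO=<ID={name},Number=1,Type=Float,'
                     f'Description="Site metric {name}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples) + "\n")
        for i, v in enumerate(cohort.variants):
            info = []
            if v.gene:
                info.append(f"GENE={v.gene}")
            info.append(f"CSQCLASS={v.consequence}")
            for name in SITE_METRIC_NAMES:
                if name in v.site_metrics:
                    info.append(f"{name}={v.site_metrics[name]:g}")
            cells = []
            for j in range(len(cohort.samples)):
                dp = int(cohort.dp[i, j])
                ad = int(cohort.ad[i, j])
                dp_s = "." if dp < 0 else str(dp)
                ad_s = ".,." if dp < 0 or ad < 0 else f"{dp - ad},{ad}"
                cells.append(f"{_GT_STR[int(cohort.gt[i, j])]}:{dp_s}:{ad_s}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t"
                     f"{v.filter_label}\t{';'.join(info)}\tGT:DP:AD\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# TSV resources
# ---------------------------------------------------------------------------

def _parse_key(fields: list[str]) -> VariantKey:
    return (fields[0], int(fields[1]), fields[2], fields[3])


def _iter_tsv(path):
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            yield header, line.split("\t")


def read_frequency_tsv(path, name: str | None = None) -> FrequencyResource:
    """Read ``chrom pos ref alt maf`` with a header row."""
    maf: dict[VariantKey, float] = {}
    for header, fields in _iter_tsv(path):
        maf[_parse_key(fields)] = float(fields[4])
    if name is None:
        name = re.sub(r"\.tsv$", "", str(path).rsplit("/", 1)[-1])
    return FrequencyResource(name=name, maf=maf)


def read_scores_tsv(path) -> PredictionScores:
    """Read predictor calls: ``chrom pos ref alt`` + one column per predictor."""
    calls: dict[VariantKey, dict[str, str]] = {}
    code = {"D": "damaging", "damaging": "damaging",
            "B": "benign", "benign": "benign",
            "U": "unknown", "unknown": "unknown", ".": "unknown"}
    for header, fields in _iter_tsv(path):
        key = _parse_key(fields)
        calls[key] = {pred: code.get(val, "unknown")
                      for pred, val in zip(header[4:], fields[4:])}
    return PredictionScores(calls=calls)


def read_annotation_tsv(path) -> dict[VariantKey, tuple[str, str]]:
    """Read ``chrom pos ref alt gene consequence``."""
    out: dict[VariantKey, tuple[str, str]] = {}
    for header, fields in _iter_tsv(path):
        out[_parse_key(fields)] = (fields[4], fields[5])
    return out


def apply_annotation(cohort: Cohort,
                     annot: dict[VariantKey, tuple[str, str]]) -> None:
    for v in cohort.variants:
        if v.key in annot:
            v.gene, v.consequence = annot[v.key]


def read_known_sites(path) -> set[VariantKey]:
    out = set()
    for header, fields in _iter_tsv(path):
        out.add(_parse_key(fields))
    return out


def read_edge_list(path) -> nx.Graph:
    """Read a gene-gene interaction edge list (geneA geneB [source])."""
    g = nx.Graph()
    for header, fields in _iter_tsv(path):
        a, b = fields[0], fields[1]
        if a == b:
            continue
        src = fields[2] if len(fields) > 2 else ""
        g.add_edge(a, b, source=src)
    return g


def read_gene_list(path) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _normalize_decimal(text: str) -> float | None:
    """Parse a printed number; European decimal commas are normalized."""
    text = text.strip()
    if text in ("", "N", "NA", "-"):
        return None
    return float(text.replace(",", "."))


def _fixture_rows(fname: str) -> list[dict[str, str]]:
    text = (_resources.files("famseq") / "fixtures" / fname).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_fixtures() -> CohortFixture:
    """Load the packaged worked-example tables (read-only copies)."""
    patients = _fixture_rows("table1_patients.tsv")

    recurrent = []
    for row in _fixture_rows("table3_recurrent_genes.tsv"):
        shared = [s.strip() for s in row["families_shared"].split(",") if s.strip()]
        single: list[tuple[str, str]] = []
        if row["families_single"].strip() not in ("0", ""):
            for item in row["families_single"].split(";"):
                fam, pat = item.split(":")
                single.append((fam.strip(), pat.strip()))
        recurrent.append({
            "gene": row["gene"],
            "families_shared": shared,
            "families_single": single,
            "n_variants": int(row["n_variants"]),
            "p_value": _normalize_decimal(row["p_value"]),
            "lod": _normalize_decimal(row["lod"]),
        })

    fat3 = []
    for row in _fixture_rows("table4_fat3_variants.tsv"):
        fat3.append({
            "family": row["family"],
            "variant": row["variant"],
            "public_db_maf": _normalize_decimal(row["public_db_maf"]),
            "exac_maf": _normalize_decimal(row["exac_maf"]),
            "mgp_maf": _normalize_decimal(row["mgp_maf"]),
            "sift": row["sift"],
            "polyphen": row["polyphen"],
            "mutation_taster": row["mutation_taster"],
            "logistic_regression": row["logistic_regression"],
        })
    return CohortFixture(patients=patients, recurrent_genes=recurrent,
                         fat3_variants=fat3)


def default_seed_genes() -> list[str]:
    """The shipped HSCR candidate-gene seed list (user-replaceable)."""
    text = (_resources.files("famseq") / "fixtures"
            / "hscr_candidate_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
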