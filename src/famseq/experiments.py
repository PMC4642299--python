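"""Reproducible evaluation experiments for the pipeline's statistical claims.

Each routine regenerates its own synthetic data from an integer seed and
returns plain numbers, so the same code backs the test suite and the
acceptance script.  Problem sizes are chosen to give stable Monte-Carlo
estimates at desk scale; they are stated in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .core_io import GenotypeCall, default_seed_genes
from .kinship import ibd_moments, select_ibd_markers, verify_pedigree
from .network import prioritize
from .pedigree import Pedigree, PedigreeMember
from .rare_damaging import filter_cascade
from .recurrence import (burden_test, cross_family_sharing_pvalue,
                         gene_sharing_table, sharing_null_probability)
from .simulate import (Architecture, SimulationConfig, default_templates,
                       mendelian_check, simulate_cohort, templates_to_pedigree)
from .variant_qc import apply_genotype_qc, qc_genotype

__all__ = [
    "template_sharing_probabilities", "mc_exact_agreement",
    "recovery_experiment", "null_calibration", "ibd_experiment",
    "burden_agreement", "qc_boundary_mismatches", "noiseless_mendelian",
    "default_cohort_summary",
]


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# sharing probability: exact vs Monte-Carlo gene dropping
# ---------------------------------------------------------------------------

def template_sharing_probabilities() -> dict[str, float]:
    """Exact null sharing probability for every shipped family template."""
    ped = templates_to_pedigree(default_templates())
    return {fam: sharing_null_probability(ped, fam, method="exact").p
            for fam in ped.families}


def mc_exact_agreement(seed: int, n_drops: int = 100_000) -> dict[str, dict]:
    """Monte-Carlo gene dropping vs exact enumeration on every template."""
    ped = templates_to_pedigree(default_templates())
    out = {}
    for k, fam in enumerate(ped.families):
        exact = sharing_null_probability(ped, fam, method="exact").p
        mc = sharing_null_probability(ped, fam, method="mc", n_drops=n_drops,
                                      seed=_subseed(seed, k)).p
        out[fam] = {"exact": exact, "mc": mc, "diff": abs(exact - mc)}
    return out


# ---------------------------------------------------------------------------
# planted-architecture recovery
# ---------------------------------------------------------------------------

def _recovery_config(model: str, seed: int, depth_mean: float,
                     error_rate: float) -> tuple[SimulationConfig, str]:
    templates = default_templates()
    if model == "dominant":
        fams = [templates[0], templates[1]]          # fam1 (parent-child) + sibs
        target = "fam1"
    else:
        fams = [templates[1], templates[2]]          # two sib families
        target = "fam2"
    genes = ("PLANTA", "PLANTB") if model == "digenic" else ("PLANTA",)
    csq = "LOF" if model == "dominant" else "missense"
    arch = Architecture(family_id=target, model=model, genes=genes,
                        consequence=csq)
    cfg = SimulationConfig(
        seed=seed, templates=fams, n_genes=24, variants_per_gene_mean=2.0,
        marker_panel_size=0, n_background_edges=20,
        depth_mean=depth_mean, error_rate=error_rate, architectures=[arch])
    return cfg, target


def _planted_recovered(model: str, report, genes: tuple[str, ...]) -> bool:
    for e in report.explanations:
        if model == "dominant" and e.kind == "dominant" and e.genes == genes:
            return True
        if model == "recessive" and e.kind == "recessive" and e.genes == genes:
            return True
        if model == "compound_het" and e.kind == "compound_het" \
                and e.genes == genes:
            return True
        if model == "digenic" and e.kind == "joint" \
                and set(genes) <= set(e.genes):
            return True
    return False


def recovery_experiment(model: str, n_reps: int = 100, seed: int = 0,
                        depth_mean: float = 35.0,
                        error_rate: float = 0.005) -> float:
    """Fraction of seeded replicates in which the planted gene(s) come back
    as a full-cosegregation explanation after the complete pipeline."""
    hits = 0
    for rep in range(n_reps):
        cfg, target = _recovery_config(model, _subseed(seed, rep),
                                       depth_mean, error_rate)
        sim = simulate_cohort(cfg)
        apply_genotype_qc(sim.cohort)
        filt = filter_cascade(sim.cohort, sim.resources, sim.scores)
        reports = prioritize(sim.cohort, filt, sim.graph,
                             default_seed_genes())
        genes = cfg.architectures[0].genes
        if model == "digenic":
            genes = tuple(sorted(genes))
        if target in reports and _planted_recovered(model, reports[target],
                                                    genes):
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# null calibration of the cross-family sharing p-value
# ---------------------------------------------------------------------------

def null_calibration(n_cohorts: int = 500, seed: int = 0, n_genes: int = 150,
                     variants_per_gene_mean: float = 3.0,
                     threshold: float = 0.05) -> dict:
    """Type-I behaviour of the sharing p-value over null cohorts.

    Every gene carried by at least one affected in at least one family is
    tested; under null transmission the p-values are super-uniform, so the
    fraction below ``threshold`` should not exceed it (binomial error aside).
    """
    family_probs = template_sharing_probabilities()
    n_tested = n_below = 0
    base = SimulationConfig(
        seed=0, n_genes=n_genes,
        variants_per_gene_mean=variants_per_gene_mean,
        marker_panel_size=0, n_background_edges=0)
    for rep in range(n_cohorts):
        cfg = replace(base, seed=_subseed(seed, rep))
        sim = simulate_cohort(cfg)
        apply_genotype_qc(sim.cohort)
        filt = filter_cascade(sim.cohort, sim.resources, sim.scores)
        table = gene_sharing_table(sim.cohort, filt)
        for gene, rec in table.items():
            if not rec["carrier_families"]:
                continue
            probs = [family_probs[f] for f in sorted(rec["carrier_families"])]
            p = cross_family_sharing_pvalue(probs, len(rec["shared_families"]))
            n_tested += 1
            n_below += p < threshold
    frac = n_below / n_tested if n_tested else 0.0
    ci_upper = threshold + 2.576 * math.sqrt(
        threshold * (1 - threshold) / max(n_tested, 1))
    return {"n_tested": n_tested, "n_below": n_below, "fraction": frac,
            "threshold": threshold, "ci_upper": ci_upper}


# ---------------------------------------------------------------------------
# IBD recovery and pedigree verification
# ---------------------------------------------------------------------------

def _misspecified_pedigree() -> tuple[list, Pedigree]:
    """Truth: two unrelated sequenced founders; claim: they are full sibs."""
    from .simulate import FamilyTemplate

    truth = FamilyTemplate("famX", (
        ("famX-A", None, None, "male", "no", True),
        ("famX-B", None, None, "male", "no", True),
    ))
    claim = Pedigree([
        PedigreeMember("famX", "famX-P1", None, None, "male", "no"),
        PedigreeMember("famX", "famX-P2", None, None, "female", "no"),
        PedigreeMember("famX", "famX-A", "famX-P1", "famX-P2", "male", "no"),
        PedigreeMember("famX", "famX-B", "famX-P1", "famX-P2", "male", "no"),
    ])
    return [truth], claim


def ibd_experiment(seed: int = 0, n_reps: int = 50,
                   n_markers: int = 5000) -> dict:
    """Moment-estimator pi_hat for sib and fourth-degree affected pairs,
    false-flag rate of pedigree verification, and misspecification detection."""
    templates = default_templates()
    ped = templates_to_pedigree(templates)
    sib_fams = ["fam2", "fam3", "fam4", "fam6", "fam8"]
    sib_vals, fourth_vals = [], []
    n_checks = n_flags = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=_subseed(seed, rep), templates=templates,
                               n_genes=1, variants_per_gene_mean=0.0,
                               marker_panel_size=n_markers,
                               n_background_edges=0)
        sim = simulate_cohort(cfg)
        g = sim.marker_genotypes
        samples = sim.cohort.samples
        founders = [s for s in samples if ped.member(s).is_founder]
        fcols = [samples.index(s) for s in founders]
        freqs = g[:, fcols].mean(axis=1) / 2.0
        kept = select_ibd_markers(g, maf_min=0.01, r2_max=0.2)
        gk, fk = g[kept], freqs[kept]
        n_chroms = 2 * len(fcols)
        for fam in sib_fams:
            a, b = ped.affected(fam)
            res = ibd_moments(gk, (samples.index(a), samples.index(b)), fk,
                              n_freq_chroms=n_chroms)
            sib_vals.append(res.pi_hat)
        a, b = ped.affected("fam7")
        res = ibd_moments(gk, (samples.index(a), samples.index(b)), fk,
                          n_freq_chroms=n_chroms)
        fourth_vals.append(res.pi_hat)
        checks = verify_pedigree(gk, samples, ped, fk,
                                 n_freq_chroms=n_chroms)
        n_checks += len(checks)
        n_flags += sum(c.flagged for c in checks)

    # misspecified pedigree: unrelated pair claimed as sibs, one replicate set
    mis_templates, claim_ped = _misspecified_pedigree()
    n_mis_flagged = 0
    n_mis = 10
    for rep in range(n_mis):
        cfg = SimulationConfig(seed=_subseed(seed, 10_000 + rep),
                               templates=mis_templates, n_genes=1,
                               variants_per_gene_mean=0.0,
                               marker_panel_size=n_markers,
                               n_background_edges=0)
        sim = simulate_cohort(cfg)
        g = sim.marker_genotypes
        freqs = g.mean(axis=1) / 2.0
        ok = (freqs > 0.01) & (freqs < 0.99)
        checks = verify_pedigree(g[ok], sim.cohort.samples, claim_ped,
                                 freqs[ok],
                                 n_freq_chroms=2 * g.shape[1])
        n_mis_flagged += sum(c.flagged for c in checks
                             if set(c.pair) == {"famX-A", "famX-B"})
    return {
        "sib_mean_pihat": float(np.mean(sib_vals)),
        "fourth_degree_mean_pihat": float(np.mean(fourth_vals)),
        "false_flag_rate": n_flags / n_checks if n_checks else 0.0,
        "misspecified_flag_rate": n_mis_flagged / n_mis,
    }


# ---------------------------------------------------------------------------
# exact burden test vs brute-force hypergeometric summation
# ---------------------------------------------------------------------------

def _brute_force_tails(n_case: int, n_bg: int, K: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-arithmetic hypergeometric tails for every feasible case count.

    Returns (ks, fisher tails P(X >= k), mid-p tails) — the independent
    oracle against which the scipy-backed test is compared.
    """
    from itertools import accumulate

    N, n = n_case + n_bg, n_case
    lo, hi = max(0, K - n_bg), min(K, n_case)
    denom = math.comb(N, n)
    nums = [math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)]
    # exact integer suffix sums (int64 overflows silently on these combs)
    suffix = list(accumulate(reversed(nums)))[::-1]
    ks = np.arange(lo, hi + 1)
    fisher = np.array([s / denom for s in suffix])
    mid = fisher - 0.5 * np.array([v / denom for v in nums])
    return ks, np.clip(fisher, 0, 1), np.clip(mid, 0, 1)


def burden_agreement(seed: int = 0, exhaustive_total: int = 40,
                     n_random: int = 1000, max_total: int = 200) -> float:
    """Max |implementation - brute force| over exhaustively enumerated small
    tables plus random tables with group totals up to ``max_total``."""
    from scipy.stats import hypergeom

    rng = np.random.default_rng(seed)
    max_diff = 0.0

    def check_table(n_case, n_bg, K):
        nonlocal max_diff
        ks, fisher, mid = _brute_force_tails(n_case, n_bg, K)
        dist = hypergeom(n_case + n_bg, K, n_case)
        got_f = np.clip(dist.sf(ks - 1), 0, 1)
        got_m = np.clip(got_f - 0.5 * dist.pmf(ks), 0, 1)
        max_diff = max(max_diff,
                       float(np.abs(got_f - fisher).max()),
                       float(np.abs(got_m - mid).max()))

    for total in range(2, exhaustive_total + 1):
        for n_case in range(1, total):
            for K in range(total + 1):
                check_table(n_case, total - n_case, K)
    for _ in range(n_random):
        n_case = int(rng.integers(1, max_total + 1))
        n_bg = int(rng.integers(1, max_total + 1))
        K = int(rng.integers(0, n_case + n_bg + 1))
        check_table(n_case, n_bg, K)
    # spot-check that the user-facing call agrees with the vectorized path
    for k, n_case, k_bg, n_bg in ((5, 16, 10, 1294), (0, 16, 10, 1294),
                                  (3, 10, 3, 10)):
        ks, fisher, mid = _brute_force_tails(n_case, n_bg, k + k_bg)
        row = int(np.flatnonzero(ks == k)[0])
        max_diff = max(
            max_diff,
            abs(burden_test(k, n_case, n_background=n_bg,
                            background_carriers=k_bg) - mid[row]),
            abs(burden_test(k, n_case, n_background=n_bg,
                            background_carriers=k_bg, mid_p=False)
                - fisher[row]))
    return max_diff


# ---------------------------------------------------------------------------
# QC boundary cases and noiseless Mendelian consistency
# ---------------------------------------------------------------------------

def qc_boundary_mismatches() -> int:
    """Disagreements between the genotype-QC rules and the printed thresholds
    on exact boundary cases (depth 4 vs 5; ratios at 0.25 / 0.95)."""
    het = ("ref", "alt")
    hom_alt = ("alt", "alt")
    hom_ref = ("ref", "ref")
    cases = [
        (GenotypeCall("s", het, 5, 2), True),     # ratio 0.4, depth 5 > 4
        (GenotypeCall("s", het, 4, 2), False),    # depth 4 is not > 4
        (GenotypeCall("s", het, 16, 4), False),   # ratio exactly 0.25
        (GenotypeCall("s", het, 16, 5), True),    # ratio above 0.25
        (GenotypeCall("s", hom_alt, 20, 19), False),  # ratio exactly 0.95
        (GenotypeCall("s", hom_alt, 20, 20), True),
        (GenotypeCall("s", hom_ref, 20, 1), False),   # ref ratio exactly 0.95
        (GenotypeCall("s", hom_ref, 20, 0), True),
        (GenotypeCall("s", hom_alt, 4, 4), False),    # depth 4 is not > 4
        (GenotypeCall("s", hom_alt, 5, 5), True),
    ]
    return sum(qc_genotype(call)[0] != want for call, want in cases)


def noiseless_mendelian(seed: int = 0) -> int:
    """Mendelian inconsistencies in a deep, error-free simulated cohort."""
    cfg = SimulationConfig(
        seed=seed, n_genes=60, variants_per_gene_mean=3.0,
        depth_mean=1000.0, error_rate=0.0, marker_panel_size=0,
        architectures=[
            Architecture("fam1", "dominant", ("PLANTD",), "LOF"),
            Architecture("fam2", "recessive", ("PLANTR",)),
            Architecture("fam8", "compound_het", ("PLANTC",)),
            Architecture("fam6", "digenic", ("PLANTX", "PLANTY")),
        ])
    sim = simulate_cohort(cfg)
    return mendelian_check(sim.cohort)


# ---------------------------------------------------------------------------
# default-cohort end-to-end summary
# ---------------------------------------------------------------------------

def default_cohort_summary(seed: int = 0, scale: float = 1.0) -> dict:
    """Run the default study-condition cohort through QC + filtering and
    summarize the per-patient rare-damaging counts and family sharing."""
    cfg = SimulationConfig(seed=seed, architectures=[
        Architecture("fam1", "dominant", ("PLANTD",), "LOF"),
        Architecture("fam5", "dominant", ("PLANTE",), "missense"),
        Architecture("fam8", "compound_het", ("PLANTC",)),
        Architecture("fam6", "digenic", ("PLANTX", "PLANTY")),
    ], marker_panel_size=0)
    if scale != 1.0:
        cfg = cfg.scaled(scale)
    sim = simulate_cohort(cfg)
    apply_genotype_qc(sim.cohort)
    filt = filter_cascade(sim.cohort, sim.resources, sim.scores)
    counts = [n for row in filt.family_rows for n in row.per_patient.values()]
    shared = {row.family_id: row.n_shared for row in filt.family_rows}
    return {
        "per_patient_mean": float(np.mean(counts)),
        "per_patient_sd": float(np.std(counts, ddof=1)),
        "n_patients": len(counts),
        "family_shared": shared,
    }
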