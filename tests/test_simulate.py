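"""The synthetic-cohort generator: determinism, truth, Mendelian behaviour."""

import numpy as np
import pytest
from scipy.stats import chisquare

from famseq.pedigree import parse_ped_text
from famseq.simulate import (Architecture, SimulationConfig, mendelian_check,
                             simulate_cohort)

from conftest import SIB_SAMPLES, build_cohort, make_variant


def _cfg(seed, **kw):
    base = dict(n_genes=30, variants_per_gene_mean=2.0, marker_panel_size=50)
    base.update(kw)
    return SimulationConfig(seed=seed, **base)


def test_seed_determinism_and_divergence(tmp_path):
    a = simulate_cohort(_cfg(1))
    b = simulate_cohort(_cfg(1))
    c = simulate_cohort(_cfg(2))
    assert np.array_equal(a.cohort.gt, b.cohort.gt)
    assert np.array_equal(a.cohort.dp, b.cohort.dp)
    assert [v.key for v in a.cohort.variants] \
        == [v.key for v in b.cohort.variants]
    assert not np.array_equal(a.cohort.gt, c.cohort.gt)
    # on-disk outputs are byte-identical too
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for name in pa:
        assert open(pa[name], "rb").read() == open(pb[name], "rb").read()


def test_noiseless_simulation_is_mendelian_consistent():
    cfg = _cfg(3, depth_mean=1000.0, error_rate=0.0, architectures=[
        Architecture("fam1", "dominant", ("PD",), "LOF"),
        Architecture("fam2", "recessive", ("PR",)),
        Architecture("fam8", "compound_het", ("PC",)),
        Architecture("fam6", "digenic", ("PX", "PY")),
    ])
    sim = simulate_cohort(cfg)
    assert mendelian_check(sim.cohort) == 0
    assert np.array_equal(sim.cohort.gt, sim.truth_gt)


def test_single_trio_inconsistency_counted(sib_pedigree):
    cohort = build_cohort([make_variant(0)], SIB_SAMPLES,
                          [[0, 0, 1, 0, 0, 0]], ped=sib_pedigree)
    assert mendelian_check(cohort) == 1     # hom-ref x hom-ref -> het child
    cohort2 = build_cohort([make_variant(0)], SIB_SAMPLES,
                           [[2, 2, 1, 2, 2, 2]], ped=sib_pedigree)
    assert mendelian_check(cohort2) == 1    # hom-alt x hom-alt -> het child


def test_inconsistency_rate_grows_with_error_rate():
    rates = []
    for err in (0.0, 0.05, 0.2):
        counts = [mendelian_check(simulate_cohort(
            _cfg(100 + s, n_genes=60, error_rate=err,
                 marker_panel_size=0)).cohort) for s in range(3)]
        rates.append(np.mean(counts))
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


def test_planted_truth_matches_genotypes():
    """Planted carriers in the truth table agree with the emitted (true)
    genotypes; the planted dominant allele reaches both affecteds."""
    cfg = _cfg(5, error_rate=0.0, depth_mean=500.0, architectures=[
        Architecture("fam1", "dominant", ("PD",), "LOF"),
        Architecture("fam8", "compound_het", ("PC",)),
    ])
    sim = simulate_cohort(cfg)
    ped = sim.cohort.pedigree
    for pv in sim.truth.planted:
        i = sim.cohort.variant_index(pv.key)
        for member, dosage in pv.expected_carriers.items():
            j = sim.cohort.sample_index(member)
            assert sim.truth_gt[i, j] == dosage
        # no sequenced member outside the carrier list carries it
        for j, s in enumerate(sim.cohort.samples):
            if ped.family_of(s) == pv.family_id \
                    and s not in pv.expected_carriers:
                assert sim.truth_gt[i, j] == 0
    dom = [pv for pv in sim.truth.planted if pv.model == "dominant"]
    assert dom and all(
        set(ped.affected(pv.family_id)) <= set(pv.expected_carriers)
        for pv in dom)


def test_unsatisfiable_architectures_error_with_family_name():
    with pytest.raises(ValueError, match="fam5"):
        simulate_cohort(_cfg(6, architectures=[
            Architecture("fam5", "compound_het", ("PC",))]))
    with pytest.raises(ValueError, match="fam2"):
        # sib family with sequenced parents cannot hide a dominant carrier
        simulate_cohort(_cfg(7, architectures=[
            Architecture("fam2", "dominant", ("PD",))]))


def test_founder_allele_frequencies_match_spectrum():
    """Chi-square goodness of fit of founder alt-allele counts across AF
    deciles is not rejected at the 1% level."""
    cfg = _cfg(8, n_genes=500, variants_per_gene_mean=4.0,
               common_fraction=0.0, marker_panel_size=0)
    sim = simulate_cohort(cfg)
    ped = sim.cohort.pedigree
    founders = [s for s in sim.cohort.samples if ped.member(s).is_founder]
    fcols = [sim.cohort.sample_index(s) for s in founders]
    counts = sim.truth_gt[:, fcols].sum(axis=1)
    n_chrom = 2 * len(fcols)
    # recover the configured AF per variant from the frequency resources
    af = np.empty(len(sim.cohort.variants))
    merged = {}
    for r in sim.resources:
        merged.update(r.maf)
    lo, hi = cfg.rare_af_range
    for i, v in enumerate(sim.cohort.variants):
        af[i] = merged.get(v.key, np.exp(0.5 * (np.log(lo) + np.log(hi))))
    known = np.array([v.key in merged for v in sim.cohort.variants])
    af, counts = af[known], counts[known]
    bins = np.quantile(af, np.linspace(0, 1, 11))
    idx = np.clip(np.digitize(af, bins[1:-1]), 0, 9)
    obs = np.array([counts[idx == b].sum() for b in range(10)])
    exp = np.array([n_chrom * af[idx == b].sum() for b in range(10)])
    # fold sparse bins together so the chi-square approximation holds
    keep = exp > 5
    stat, p = chisquare(obs[keep], exp[keep] * obs[keep].sum()
                        / exp[keep].sum())
    assert p > 0.01


def test_depth_model_mean_within_five_percent():
    cfg = _cfg(9, n_genes=300, variants_per_gene_mean=4.0,
               marker_panel_size=0)
    sim = simulate_cohort(cfg)
    assert sim.cohort.dp.size >= 10_000
    assert abs(sim.cohort.dp.mean() - cfg.depth_mean) / cfg.depth_mean < 0.05
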