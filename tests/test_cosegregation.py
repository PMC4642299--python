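"""Within-family sharing, inheritance-model fits, compound hets, joint sets."""

import itertools

import networkx as nx
import numpy as np
import pytest

from famseq.cosegregation import (find_compound_het, fit_dominant,
                                  fit_recessive, fit_x_linked,
                                  joint_cosegregation, shared_variants)
from famseq.pedigree import parse_ped_text

from conftest import SIB_SAMPLES, build_cohort, make_variant

# sample order: fa mo a1 a2 u1 u2


def _coh(ped, rows, variants=None):
    variants = variants or [make_variant(i) for i in range(len(rows))]
    return build_cohort(variants, SIB_SAMPLES, rows, ped=ped)


def test_shared_variants_basic(sib_pedigree):
    cohort = _coh(sib_pedigree, [
        [0, 1, 1, 1, 0, 0],     # both affected het -> shared
        [0, 1, 1, 0, 0, 0],     # one affected only -> not shared
    ])
    res = shared_variants(cohort, "fam")
    assert res.shared_idx.tolist() == [0]
    assert res.n_shared == 1
    assert set(res.carriers[0]) == {"mo", "a1", "a2"}


def test_shared_lof_subset_counted(sib_pedigree):
    variants = [make_variant(0, consequence="LOF", alt="GA"), make_variant(1)]
    cohort = _coh(sib_pedigree, [[0, 0, 1, 1, 0, 0], [0, 0, 1, 1, 0, 0]],
                  variants)
    res = shared_variants(cohort, "fam")
    assert res.n_shared == 2 and res.n_shared_lof == 1


@pytest.mark.parametrize("g1,g2",
                         list(itertools.product((-1, 0, 1, 2), repeat=2)))
def test_shared_truth_table_over_genotype_grid(sib_pedigree, g1, g2):
    """Strict mode: shared iff both affected genotyped and carrying; lenient:
    missing is unknown, shared iff no genotyped affected lacks it and one
    carries."""
    cohort = _coh(sib_pedigree, [[0, 0, g1, g2, 0, 0]])
    strict = shared_variants(cohort, "fam", strict=True).n_shared == 1
    lenient = shared_variants(cohort, "fam", strict=False).n_shared == 1
    assert strict == (g1 > 0 and g2 > 0)
    assert lenient == ((g1 > 0 or g1 < 0) and (g2 > 0 or g2 < 0)
                       and (g1 > 0 or g2 > 0))


def test_shared_requires_two_affected(sib_pedigree):
    cohort = build_cohort([make_variant(0)], ["fa", "mo", "a1"],
                          [[0, 0, 1]], ped=sib_pedigree)
    with pytest.raises(ValueError, match="affected"):
        shared_variants(cohort, "fam")


def test_dominant_fits(sib_pedigree):
    cohort = _coh(sib_pedigree, [
        [0, 0, 1, 1, 0, 0],      # clean full dominant
        [1, 0, 1, 1, 0, 0],      # unaffected father carries
        [-1, -1, 1, 1, -1, -1],  # everything but affecteds missing
        [0, 0, 0, 1, 0, 0],      # affected non-carrier
    ])
    full = fit_dominant(cohort, "fam", 0)
    assert full.segregation == "full" and full.violations == []
    partial = fit_dominant(cohort, "fam", 1)
    assert partial.segregation == "partial"
    assert partial.violations == ["unaffected carrier fa"]
    assert fit_dominant(cohort, "fam", 2).segregation == "full"
    none = fit_dominant(cohort, "fam", 3)
    assert none.segregation == "none"
    assert "affected non-carrier a1" in none.violations
    # relaxed penetrance tolerates one unaffected carrier
    relaxed = fit_dominant(cohort, "fam", 1, max_unaffected_carriers=1)
    assert relaxed.segregation == "full" and relaxed.tolerated


def test_recessive_fits(sib_pedigree):
    cohort = _coh(sib_pedigree, [
        [1, 1, 2, 2, 1, 0],      # textbook: parents het, affecteds hom
        [0, 1, 2, 2, 0, 0],      # father hom-ref under hom-alt child
        [1, 1, 2, 2, 2, 0],      # unaffected sib hom-alt
    ])
    assert fit_recessive(cohort, "fam", 0).segregation == "full"
    bad = fit_recessive(cohort, "fam", 1)
    assert bad.segregation == "none"
    assert any(v.startswith("mendelian") for v in bad.violations)
    part = fit_recessive(cohort, "fam", 2)
    assert part.segregation == "partial"
    assert "unaffected hom-alt u1" in part.violations


def test_compound_het_phasing(sib_pedigree):
    variants = [make_variant(i, gene="G1") for i in range(3)]
    # v0 from father only, v1 from mother only -> trans
    cohort = _coh(sib_pedigree, [
        [1, 0, 1, 1, 0, 0],
        [0, 1, 1, 1, 0, 0],
        [1, 1, 1, 1, 0, 0],      # father carries v0 and v2 -> cis-ambiguous
    ], variants)
    fits = find_compound_het(cohort, "fam", "G1", np.arange(3))
    pairs = {f.variants for f in fits}
    trans_pair = tuple(sorted([variants[0].key, variants[1].key]))
    assert trans_pair in pairs
    got = next(f for f in fits if f.variants == trans_pair)
    assert got.phase == "trans" and got.segregation == "full"
    # any pair involving v2 with v0 is rejected (father carries both)
    assert tuple(sorted([variants[0].key, variants[2].key])) not in pairs


def test_compound_het_symmetry_and_dedup(sib_pedigree):
    variants = [make_variant(i, gene="G1") for i in range(2)]
    cohort = _coh(sib_pedigree, [
        [1, 0, 1, 1, 0, 0],
        [0, 1, 1, 1, 0, 0],
    ], variants)
    fits_a = find_compound_het(cohort, "fam", "G1", np.array([0, 1]))
    fits_b = find_compound_het(cohort, "fam", "G1", np.array([1, 0]))
    assert len(fits_a) == len(fits_b) == 1
    assert fits_a[0].variants == fits_b[0].variants
    assert fits_a[0].variants == tuple(sorted(fits_a[0].variants))


def test_compound_het_hom_pair_not_reported(sib_pedigree):
    """A homozygote is not a compound het (that is the recessive model)."""
    variants = [make_variant(0, gene="G1"), make_variant(1, gene="G1")]
    cohort = _coh(sib_pedigree, [
        [1, 1, 2, 2, 0, 0],      # hom, not het
        [0, 1, 1, 1, 0, 0],
    ], variants)
    assert find_compound_het(cohort, "fam", "G1", np.arange(2)) == []


X_PED = """\
fam fa 0 0 1 1
fam mo 0 0 2 1
fam a1 fa mo 1 2
fam a2 fa mo 1 2
fam u1 fa mo 1 1
fam u2 fa mo 2 1
"""


def test_x_linked_fits():
    ped = parse_ped_text(X_PED)
    variants = [make_variant(i, chrom="X") for i in range(2)]
    cohort = build_cohort(variants, SIB_SAMPLES, [
        [0, 1, 1, 1, 0, 0],      # affected brothers hemizygous, mother het
        [0, 1, 1, 1, 1, 0],      # unaffected brother carries
    ], ped=ped)
    assert fit_x_linked(cohort, "fam", 0).segregation == "full"
    part = fit_x_linked(cohort, "fam", 1)
    assert part.segregation == "partial"
    assert "unaffected male carrier u1" in part.violations
    auto = build_cohort([make_variant(9, chrom="2")], SIB_SAMPLES,
                        [[0, 1, 1, 1, 0, 0]], ped=ped)
    with pytest.raises(ValueError, match="X chromosome"):
        fit_x_linked(auto, "fam", 0)


def _joint_cohort(sib_pedigree, gene_rows):
    variants = [make_variant(i, gene=g) for i, (g, _) in enumerate(gene_rows)]
    rows = [r for _, r in gene_rows]
    return _coh(sib_pedigree, rows, variants), np.arange(len(gene_rows))


def test_joint_identical_combination(sib_pedigree):
    graph = nx.Graph([("GA", "GB")])
    cohort, idx = _joint_cohort(sib_pedigree, [
        ("GA", [1, 0, 1, 1, 0, 0]),
        ("GB", [0, 1, 1, 1, 0, 0]),
    ])
    res = joint_cosegregation(cohort, "fam", idx, graph, [], k=2)
    assert res.explained and res.identical_across
    assert res.per_affected["a1"][0].genes == ("GA", "GB")


def test_joint_patient_specific_combinations(sib_pedigree):
    graph = nx.Graph([("GA", "GB"), ("GA2", "GC")])
    cohort, idx = _joint_cohort(sib_pedigree, [
        ("GA", [1, 0, 1, 0, 0, 0]),
        ("GB", [0, 1, 1, 0, 0, 0]),
        ("GA2", [1, 0, 0, 1, 0, 0]),
        ("GC", [0, 1, 0, 1, 0, 0]),
    ])
    res = joint_cosegregation(cohort, "fam", idx, graph, [], k=2)
    assert res.explained and not res.identical_across


def test_joint_seed_gene_route(sib_pedigree):
    """Two genes linked only through a common seed gene form a combination."""
    graph = nx.Graph([("GA", "SEED"), ("GB", "SEED")])
    cohort, idx = _joint_cohort(sib_pedigree, [
        ("GA", [1, 0, 1, 1, 0, 0]),
        ("GB", [0, 1, 1, 1, 0, 0]),
    ])
    assert not joint_cosegregation(cohort, "fam", idx, graph, [],
                                   k=2).explained
    assert joint_cosegregation(cohort, "fam", idx, graph, ["SEED"],
                               k=2).explained


def test_joint_degenerate_k1_and_empty_graph(sib_pedigree):
    cohort, idx = _joint_cohort(sib_pedigree, [
        ("GA", [1, 0, 1, 1, 0, 0]),
        ("GA", [0, 1, 1, 1, 0, 0]),
        ("GB", [0, 1, 1, 0, 0, 0]),
    ])
    empty = nx.Graph()
    # k=1 reduces to a single-gene carrier report
    res1 = joint_cosegregation(cohort, "fam", idx, empty, [], k=1)
    assert {c.genes for c in res1.per_affected["a1"]} == {("GA",), ("GB",)}
    # empty graph, k=2: explained iff one gene carries >= 2 variants in
    # every affected
    res2 = joint_cosegregation(cohort, "fam", idx, empty, [], k=2)
    assert res2.explained
    assert all(c.genes == ("GA",) for v in res2.per_affected.values()
               for c in v)
    # drop one GA variant from a2 -> no longer explained
    cohort.gt[1, 3] = 0
    res3 = joint_cosegregation(cohort, "fam", idx, empty, [], k=2)
    assert not res3.explained


def test_joint_flags_unaffected_full_combination(sib_pedigree):
    graph = nx.Graph([("GA", "GB")])
    cohort, idx = _joint_cohort(sib_pedigree, [
        ("GA", [1, 0, 1, 1, 1, 0]),
        ("GB", [0, 1, 1, 1, 1, 0]),
    ])
    res = joint_cosegregation(cohort, "fam", idx, graph, [], k=2)
    assert res.explained
    assert res.flagged_unaffected == ["u1"]


def test_shared_superset_of_full_fits(sib_pedigree):
    """Every variant any model reports full is in the family's shared set."""
    rng = np.random.default_rng(5)
    variants = [make_variant(i, gene=f"G{i % 4}") for i in range(30)]
    gt = rng.integers(-1, 3, size=(30, 6)).astype(np.int8)
    cohort = build_cohort(variants, SIB_SAMPLES, gt, ped=sib_pedigree)
    share = set(shared_variants(cohort, "fam",
                                strict=False).shared_idx.tolist())
    for i in range(30):
        for fit_fn in (fit_dominant, fit_recessive):
            if fit_fn(cohort, "fam", i).segregation == "full":
                assert i in share
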