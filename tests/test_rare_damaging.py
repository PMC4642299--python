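"""The rare-damaging filtering cascade and its cohort-level exclusion."""

import numpy as np
import pytest

from famseq.core_io import FrequencyResource, PredictionScores
from famseq.rare_damaging import (classify_damaging,
                                  exclude_cross_family_recurrent,
                                  filter_cascade, is_rare)
from famseq.simulate import SimulationConfig, simulate_cohort
from famseq.variant_qc import apply_genotype_qc

from conftest import make_variant


def test_is_rare_requires_every_database():
    v = make_variant(0)
    db1 = FrequencyResource("db1", {v.key: 0.002})
    db2 = FrequencyResource("db2", {})                 # absent = rare
    db3 = FrequencyResource("db3", {v.key: 0.011})
    assert is_rare(v, [db1, db2])
    assert not is_rare(v, [db1, db3])
    assert is_rare(v, [db3], threshold=1.0)            # vacuous bound
    with pytest.raises(ValueError):
        is_rare(v, [])


def test_classify_damaging_consensus():
    lof = make_variant(0, consequence="LOF", alt="GA")
    missense = make_variant(1)
    syn = make_variant(2, consequence="synonymous")
    scores = PredictionScores({
        missense.key: {"Polyphen2": "damaging", "Sift": "damaging",
                       "MutationTaster": "damaging", "PhyloP": "benign",
                       "LikelihoodRatio": "unknown"},
        syn.key: {p: "damaging" for p in ("Polyphen2", "Sift",
                                          "MutationTaster", "PhyloP",
                                          "LikelihoodRatio")},
    })
    assert classify_damaging(lof, PredictionScores({}))   # LOF needs no votes
    assert classify_damaging(missense, scores)            # 3 of 4 known vote D
    assert not classify_damaging(missense, scores, min_votes=4)
    assert not classify_damaging(syn, scores)             # synonymous excluded
    other = make_variant(3, consequence="other")
    assert not classify_damaging(other, scores)


def test_cross_family_exclusion_rule():
    key = ("1", 100, "G", "T")
    assert not exclude_cross_family_recurrent(key, {"f1": True, "f3": True})
    assert exclude_cross_family_recurrent(key, {"f1": True, "f3": False})
    assert exclude_cross_family_recurrent(key, {"f1": True})


def _small_sim(seed=31, **kw):
    cfg = SimulationConfig(seed=seed, n_genes=40, variants_per_gene_mean=3.0,
                           marker_panel_size=0, **kw)
    sim = simulate_cohort(cfg)
    apply_genotype_qc(sim.cohort)
    return sim


def test_cascade_matches_bruteforce_predicate_composition():
    """Per-patient lists equal an independent re-application of the four
    predicates in sequence."""
    sim = _small_sim()
    cohort = sim.cohort
    filt = filter_cascade(cohort, sim.resources, sim.scores)
    ped = cohort.pedigree

    # brute force, one variant at a time
    fams = list(ped.families)
    per_variant = []
    for i, v in enumerate(cohort.variants):
        exonic = v.consequence in ("LOF", "missense", "synonymous")
        rare = is_rare(v, sim.resources)
        damaging = classify_damaging(v, sim.scores)
        per_variant.append(exonic and rare and damaging)
    presence = {}
    for i, ok in enumerate(per_variant):
        if not ok:
            continue
        fams_with = {ped.family_of(s) for j, s in enumerate(cohort.samples)
                     if cohort.gt[i, j] > 0}
        presence[i] = fams_with
    kept = {i for i, fams_with in presence.items() if len(fams_with) < 2}
    assert set(filt.kept_idx.tolist()) == kept

    for fam in fams:
        for patient in ped.affected(fam):
            j = cohort.sample_index(patient)
            want = sorted(i for i in kept if cohort.gt[i, j] > 0)
            assert filt.per_patient[patient].tolist() == want

    # re-verification: every emitted variant satisfies all predicates
    for i in filt.kept_idx:
        v = cohort.variants[int(i)]
        assert v.consequence in ("LOF", "missense", "synonymous")
        assert is_rare(v, sim.resources)
        assert classify_damaging(v, sim.scores)


def test_per_variant_predicates_are_order_insensitive():
    sim = _small_sim(seed=32)
    cohort = sim.cohort
    masks = {
        "exonic": np.array([v.consequence in ("LOF", "missense", "synonymous")
                            for v in cohort.variants]),
        "rare": np.array([is_rare(v, sim.resources) for v in cohort.variants]),
        "damaging": np.array([classify_damaging(v, sim.scores)
                              for v in cohort.variants]),
    }
    import itertools
    combined = [np.logical_and.reduce([masks[k] for k in order])
                for order in itertools.permutations(masks)]
    for other in combined[1:]:
        assert np.array_equal(combined[0], other)


def test_common_planted_lof_is_filtered_out():
    """A MAF-0.05 LOF allele never reaches a patient list."""
    sim = _small_sim(seed=33)
    cohort = sim.cohort
    common = make_variant(999, chrom="9", pos=999_999, gene="COMMONG",
                          consequence="LOF", alt="GA")
    cohort.variants.append(common)
    cohort.gt = np.vstack([cohort.gt,
                           np.ones(len(cohort.samples), dtype=np.int8)])
    cohort.dp = np.vstack([cohort.dp,
                           np.full(len(cohort.samples), 40, dtype=np.int32)])
    cohort.ad = np.vstack([cohort.ad,
                           np.full(len(cohort.samples), 20, dtype=np.int32)])
    cohort._key_index[common.key] = cohort.n_variants - 1
    resources = [FrequencyResource(r.name, {**r.maf, common.key: 0.05})
                 for r in sim.resources]
    filt = filter_cascade(cohort, resources, sim.scores)
    for idxs in filt.per_patient.values():
        assert cohort.n_variants - 1 not in idxs


def test_empty_cohort_all_zero_counts(sib_pedigree):
    from conftest import build_cohort

    cohort = build_cohort([], ["fa", "mo", "a1", "a2", "u1", "u2"],
                          np.empty((0, 6)), ped=sib_pedigree)
    filt = filter_cascade(cohort, [FrequencyResource("db", {})],
                          PredictionScores({}))
    assert len(filt.kept_idx) == 0
    assert all(n == 0 for row in filt.family_rows
               for n in row.per_patient.values())
    assert all(row.n_shared == 0 for row in filt.family_rows)


def test_family_removal_only_acts_through_exclusion():
    """Dropping one family never changes another family's list except via
    the cross-family recurrence exclusion."""
    sim = _small_sim(seed=34)
    cohort = sim.cohort
    filt_all = filter_cascade(cohort, sim.resources, sim.scores)
    # remove fam8's samples
    ped = cohort.pedigree
    keep_cols = [j for j, s in enumerate(cohort.samples)
                 if ped.family_of(s) != "fam8"]
    from famseq.core_io import Cohort

    sub = Cohort([v for v in cohort.variants],
                 [cohort.samples[j] for j in keep_cols],
                 cohort.gt[:, keep_cols], cohort.dp[:, keep_cols],
                 cohort.ad[:, keep_cols], pedigree=ped)
    filt_sub = filter_cascade(sub, sim.resources, sim.scores)
    excluded_keys = set(filt_all.excluded_recurrent) \
        | set(filt_sub.excluded_recurrent)
    for patient, idxs in filt_all.per_patient.items():
        if ped.family_of(patient) == "fam8":
            continue
        a = {cohort.variants[int(i)].key for i in idxs}
        b = {sub.variants[int(i)].key for i in filt_sub.per_patient[patient]}
        assert a.symmetric_difference(b) <= excluded_keys
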