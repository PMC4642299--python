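"""Knowledge-layer linking, prioritization reports, pipeline orchestration."""

import json
import os

import networkx as nx
import numpy as np
import pytest

from famseq.core_io import CohortFixture, default_seed_genes
from famseq.network import link_candidates, prioritize
from famseq.pipeline import RunConfig, cohort_summary, genotype_tally, \
    run_pipeline
from famseq.rare_damaging import filter_cascade
from famseq.simulate import (Architecture, SimulationConfig, default_templates,
                             simulate_cohort)
from famseq.variant_qc import apply_genotype_qc


def toy_graph():
    return nx.Graph([("SEED1", "A"), ("A", "B"), ("B", "C")])


def test_link_candidates_bfs_distances():
    g = toy_graph()
    out = link_candidates(["SEED1", "A", "B", "C", "Z"], g, ["SEED1"],
                          max_dist=1)
    assert out["SEED1"].linked and out["SEED1"].distance == 0
    assert out["A"].linked and out["A"].distance == 1
    assert not out["B"].linked and out["B"].distance is None
    assert not out["Z"].linked
    out2 = link_candidates(["B"], g, ["SEED1"], max_dist=2)
    assert out2["B"].linked and out2["B"].distance == 2


def _run_sim(cfg):
    sim = simulate_cohort(cfg)
    apply_genotype_qc(sim.cohort)
    filt = filter_cascade(sim.cohort, sim.resources, sim.scores)
    return sim, filt


def test_planted_compound_het_yields_single_ch_explanation():
    """One variant per background gene, so the only possible compound het is
    the planted one."""
    templates = default_templates()[1:3]
    cfg = SimulationConfig(seed=51, templates=templates, n_genes=10,
                           variants_per_gene_mean=1.0, marker_panel_size=0,
                           error_rate=0.0, depth_mean=200.0,
                           architectures=[Architecture(
                               "fam2", "compound_het", ("PC",))])
    sim, filt = _run_sim(cfg)
    reports = prioritize(sim.cohort, filt, sim.graph, default_seed_genes())
    ch = [e for e in reports["fam2"].explanations if e.kind == "compound_het"]
    assert len(ch) == 1
    assert ch[0].genes == ("PC",)
    assert reports["fam2"].status == "explained"


def test_family_with_no_surviving_variants_unexplained():
    cfg = SimulationConfig(seed=52, n_genes=6, variants_per_gene_mean=1.0,
                           marker_panel_size=0, lof_fraction=0.0,
                           missense_fraction=0.0, synonymous_fraction=1.0)
    sim, filt = _run_sim(cfg)
    assert len(filt.kept_idx) == 0           # synonymous variants never pass
    reports = prioritize(sim.cohort, filt, sim.graph, default_seed_genes())
    assert all(r.status == "unexplained" for r in reports.values())


def test_prioritize_is_deterministic():
    cfg = SimulationConfig(seed=53, n_genes=25, variants_per_gene_mean=2.0,
                           marker_panel_size=0,
                           architectures=[Architecture(
                               "fam8", "compound_het", ("PC",))])
    sim, filt = _run_sim(cfg)
    r1 = prioritize(sim.cohort, filt, sim.graph, default_seed_genes())
    r2 = prioritize(sim.cohort, filt, sim.graph, default_seed_genes())
    for fam in r1:
        assert [e.sort_key() for e in r1[fam].explanations] \
            == [e.sort_key() for e in r2[fam].explanations]
        # ranking classes are ordered recurrent < monogenic < CH < joint
        order = [e.sort_key()[0] for e in r1[fam].explanations]
        assert order == sorted(order)


def test_genotype_tally_edge_cases(fixture_tables):
    tally = genotype_tally(fixture_tables)
    assert sum(tally["fractions"].values()) == pytest.approx(1.0)
    uniform = CohortFixture(
        patients=[{"family_id": "1", "gender": "Male", "rs2435357": "T/T"}] * 4,
        recurrent_genes=[], fat3_variants=[])
    t2 = genotype_tally(uniform)
    assert t2["fractions"] == {"T/T": 1.0}
    with pytest.raises(KeyError):
        genotype_tally(fixture_tables, marker="rs0000000")


def test_cohort_summary_counts_from_rows(fixture_tables):
    s = cohort_summary(fixture_tables)
    assert s == {"n_patients": 16, "n_male": 12, "n_female": 4,
                 "n_families": 8}
    empty = cohort_summary(CohortFixture([], [], []))
    assert empty == {"n_patients": 0, "n_male": 0, "n_female": 0,
                     "n_families": 0}


def test_run_pipeline_outputs_and_determinism(tmp_path):
    """All stage outputs exist and a rerun is byte-identical."""
    sim_cfg = SimulationConfig(
        seed=4, n_genes=120, variants_per_gene_mean=3.0,
        marker_panel_size=400,
        architectures=[Architecture("fam8", "compound_het", ("PC",))])
    paths = {}
    for run_dir in ("r1", "r2"):
        cfg = RunConfig(seed=4, outdir=str(tmp_path / run_dir),
                        simulation=sim_cfg)
        paths[run_dir] = run_pipeline(cfg)
    expected = {"qc_metrics.json", "filtered.tsv", "table2_like.tsv",
                "ibd.tsv", "table3_like.tsv", "report.json",
                "mendelian.json", "run_log.txt"}
    assert set(paths["r1"]) == expected
    for name in expected:
        assert os.path.exists(paths["r1"][name])
        if name != "run_log.txt":
            assert open(paths["r1"][name], "rb").read() \
                == open(paths["r2"][name], "rb").read()
    report = json.load(open(paths["r1"]["report.json"]))
    assert "fam8" in report
    kinds = {e["kind"] for e in report["fam8"]["explanations"]}
    assert "compound_het" in kinds
    # the run log records the thresholds actually applied
    log = open(paths["r1"]["run_log.txt"]).read()
    for token in ("depth>4", "het_ratio>0.25", "hom_ratio>0.95",
                  "maf_threshold\t<0.01", "alpha\t0.05"):
        assert token in log


def test_run_config_from_yaml(tmp_path):
    y = tmp_path / "run.yaml"
    y.write_text("seed: 9\noutdir: out\nmaf_threshold: 0.005\n"
                 "min_votes: 4\n")
    cfg = RunConfig.from_yaml(y)
    assert cfg.seed == 9 and cfg.maf_threshold == 0.005 and cfg.min_votes == 4
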