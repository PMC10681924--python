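"""Generator determinism and manifest truthfulness, verified with the
pipeline's own parsers."""

import json

import numpy as np
import pytest

from netpharm import bioassay_stats as bs
from netpharm import compound_screen as cs
from netpharm import enrichment as en
from netpharm import ppi_core as pc
from netpharm import target_sets as ts
from netpharm.synthetic_data import (
    SyntheticConfig,
    ValidationError,
    gen_compounds,
    gen_gene_sets,
    gen_plate,
    gen_ppi,
    gen_target_universe,
    generate_all,
)


class TestConfig:
    def test_density_ordering_enforced(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(core_density=0.03, periphery_density=0.9)

    def test_overlap_cannot_exceed_query(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(planted_term_overlap=30, query_size=20)


class TestCompoundsGenerator:
    def test_exact_pass_count(self, tmp_path):
        cfg = SyntheticConfig(seed=1, n_compounds=20, admet_pass_fraction=0.5)
        man = gen_compounds(cfg, tmp_path / "c.tsv")
        pairs = cs.parse_compound_table(tmp_path / "c.tsv")
        passed = cs.admet_filter(pairs)
        assert len(passed) == man["n_pass"] == 10
        assert sorted(r.name for r in passed) == sorted(man["passing_compounds"])

    def test_pass_fraction_one_retains_all(self, tmp_path):
        cfg = SyntheticConfig(seed=2, n_compounds=8, admet_pass_fraction=1.0)
        gen_compounds(cfg, tmp_path / "c.tsv")
        pairs = cs.parse_compound_table(tmp_path / "c.tsv")
        assert len(cs.admet_filter(pairs)) == 8

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=3)
        gen_compounds(cfg, tmp_path / "a.tsv")
        gen_compounds(cfg, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_peak_areas_above_default_threshold(self, tmp_path):
        gen_compounds(SyntheticConfig(seed=4), tmp_path / "c.tsv")
        pairs = cs.parse_compound_table(tmp_path / "c.tsv")
        assert len(cs.filter_peaks([r for r, _ in pairs])) == len(pairs)


class TestTargetGenerator:
    def test_shared_core_present_in_every_source(self, tmp_path):
        cfg = SyntheticConfig(seed=5, overlap_gene_count=25)
        man = gen_target_universe(cfg, tmp_path)
        sets = [
            ts.load_gene_list(tmp_path / f"source_{i}.txt", f"source_{i}")[0]
            for i in range(1, cfg.n_sources + 1)
        ]
        inter = set.intersection(*(set(s.genes) for s in sets))
        assert len(inter) >= 25

    def test_manifest_counts_verifiable_by_reload(self, tmp_path):
        cfg = SyntheticConfig(seed=6)
        man = gen_target_universe(cfg, tmp_path)
        sets = {}
        for i in range(1, cfg.n_sources + 1):
            s, _ = ts.load_gene_list(tmp_path / f"source_{i}.txt", f"source_{i}")
            sets[f"source_{i}"] = set(s.genes)
            assert len(s.genes) == man["source_sizes"][f"source_{i}"]
        union, counts = ts.union_disease_targets(
            [ts.TargetSet(name=k, genes=frozenset(v), kind="disease") for k, v in sets.items()]
        )
        assert counts["union"] == man["union_size"]
        for key, n in man["pairwise_intersections"].items():
            a, b = key.split("&")
            assert len(sets[a] & sets[b]) == n

    def test_planted_common_targets_exact(self, tmp_path):
        cfg = SyntheticConfig(seed=7)
        man = gen_target_universe(cfg, tmp_path)
        cmap = ts.load_target_map(tmp_path / "drug_targets.tsv", score_floor=0.8)
        drug = ts.TargetSet(name="drug", genes=cmap.all_targets(), kind="drug")
        union = ts.TargetSet(name="u", genes=frozenset(man["union"]), kind="disease")
        common = ts.intersect_drug_disease(drug, union)
        assert sorted(common.genes) == man["common_targets"]

    def test_disjoint_mode_union_is_sum(self, tmp_path):
        cfg = SyntheticConfig(seed=8, disjoint_sources=True, source_sizes=(30, 20, 10), n_sources=3)
        man = gen_target_universe(cfg, tmp_path)
        assert man["union_size"] == 60

    def test_single_source_union_is_itself(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_sources=1, source_sizes=(40,))
        man = gen_target_universe(cfg, tmp_path)
        assert man["union_size"] == man["source_sizes"]["source_1"]


class TestPpiGenerator:
    def test_same_seed_identical_edges(self, tmp_path):
        cfg = SyntheticConfig(seed=10)
        gen_ppi(cfg, tmp_path / "a.tsv")
        gen_ppi(cfg, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_manifest_edge_count_matches_file(self, tmp_path):
        cfg = SyntheticConfig(seed=11)
        man = gen_ppi(cfg, tmp_path / "e.tsv")
        lines = [l for l in (tmp_path / "e.tsv").read_text().splitlines() if l.strip()]
        assert len(lines) == man["n_edges"]

    def test_null_model_allowed_at_equal_densities(self, tmp_path):
        cfg = SyntheticConfig(seed=12, core_density=0.5, periphery_density=0.03)
        man = gen_ppi(cfg, tmp_path / "e.tsv")
        assert len(man["core_nodes"]) == cfg.ppi_core_size


class TestGeneSetGenerator:
    def test_planted_term_is_top_hit(self, tmp_path):
        cfg = SyntheticConfig(seed=13)
        man = gen_gene_sets(cfg, tmp_path / "c.gmt", tmp_path / "q.txt")
        q, _ = ts.load_gene_list(tmp_path / "q.txt", "q", "drug")
        recs = en.run_ora(q, en.read_gmt(tmp_path / "c.gmt"))
        assert recs[0].term_id == man["planted_term"]

    def test_zero_overlap_keeps_planted_out_of_results(self, tmp_path):
        cfg = SyntheticConfig(seed=14, planted_term_overlap=0)
        man = gen_gene_sets(cfg, tmp_path / "c.gmt", tmp_path / "q.txt")
        q, _ = ts.load_gene_list(tmp_path / "q.txt", "q", "drug")
        recs = en.run_ora(q, en.read_gmt(tmp_path / "c.gmt"))
        assert man["planted_term"] not in {r.term_id for r in recs}

    def test_same_seed_identical_gmt(self, tmp_path):
        cfg = SyntheticConfig(seed=15)
        gen_gene_sets(cfg, tmp_path / "a.gmt")
        gen_gene_sets(cfg, tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()


class TestPlateGenerator:
    def test_noiseless_plate_recovers_truth(self, tmp_path):
        cfg = SyntheticConfig(seed=16, od_noise_sd=0.0)
        man = gen_plate(cfg, tmp_path / "p.tsv")
        d, o, b, c = bs.read_plate(tmp_path / "p.tsv")
        fit = bs.fit_ic50(d, bs.plate_viability(d, o, b, c))
        assert fit.ic50 == pytest.approx(man["ic50_true"], rel=1e-3)

    def test_same_seed_identical_plate(self, tmp_path):
        cfg = SyntheticConfig(seed=17)
        gen_plate(cfg, tmp_path / "a.tsv")
        gen_plate(cfg, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestGenerateAll:
    def test_manifest_written_and_core_inside_common(self, tmp_path):
        man = generate_all(SyntheticConfig(seed=18), tmp_path)
        reloaded = json.loads((tmp_path / "manifest.json").read_text())
        assert reloaded["targets"]["n_common"] == man["targets"]["n_common"]
        assert set(man["ppi"]["core_nodes"]) <= set(man["targets"]["common_targets"])
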