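import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from crosspath.io import write_gmt
from crosspath.simulate import (
    ConfigError,
    PlannedSet,
    PlantedSet,
    SharePlan,
    SimConfig,
    gen_bundle,
    gen_expression_trait,
    gen_gene_sets,
    gen_genome,
    gen_gwas,
    gen_network,
    gen_species_pair,
    gene_ids,
)


def small_config(**kwargs):
    defaults = dict(n_genes=60, n_markers=500, block_size=5, cis_per_gene=2,
                    trans_fraction=0.0, n_sets=5, set_size_range=(5, 15), seed=0)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestSimConfig:
    @pytest.mark.parametrize("field,value", [
        ("n_genes", 0), ("n_markers", -1), ("block_size", 0),
        ("cis_per_gene", 0), ("trans_fraction", 1.5), ("species_tag", "rat"),
    ])
    def test_invalid_fields_named(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            small_config(**{field: value})

    def test_set_size_range_bounds(self):
        with pytest.raises(ConfigError, match="set_size_range"):
            small_config(set_size_range=(5, 100))

    def test_planted_alpha_bounds(self):
        ids = gene_ids(small_config())
        with pytest.raises(ConfigError, match="enrichment_alpha"):
            PlantedSet("P", tuple(ids[:5]), enrichment_alpha=0.0)

    def test_planted_unknown_gene(self):
        with pytest.raises(ConfigError, match="universe"):
            small_config(planted_sets=(PlantedSet("P", ("NOPE",)),))


class TestGenGenome:
    def test_block_count_by_ceiling(self):
        cfg = small_config(n_markers=100, block_size=5)
        _, ld, _ = gen_genome(cfg)
        assert len(set(ld.values())) == 20

    def test_last_block_may_be_smaller(self):
        cfg = small_config(n_markers=101, block_size=5)
        _, ld, _ = gen_genome(cfg)
        assert len(set(ld.values())) == 21

    def test_forced_row_count_no_trans(self):
        cfg = small_config(n_genes=50, n_markers=200, cis_per_gene=2,
                           trans_fraction=0.0)
        _, _, eqtl = gen_genome(cfg)
        assert len(eqtl) == 100
        assert (eqtl["CIS_TRANS"] == "cis").all()

    def test_trans_count(self):
        cfg = small_config(n_genes=50, trans_fraction=0.5)
        _, _, eqtl = gen_genome(cfg)
        assert (eqtl["CIS_TRANS"] == "trans").sum() == 25

    def test_deterministic_byte_identical(self):
        cfg = small_config(trans_fraction=0.3)
        _, ld1, eqtl1 = gen_genome(cfg)
        _, ld2, eqtl2 = gen_genome(cfg)
        assert ld1 == ld2
        assert eqtl1.to_csv() == eqtl2.to_csv()

    def test_cis_markers_distinct_per_gene(self):
        cfg = small_config(n_genes=30, n_markers=300, cis_per_gene=3)
        _, _, eqtl = gen_genome(cfg)
        per_gene = eqtl.groupby("GENE")["MARKER"].nunique()
        assert (per_gene == 3).all()


class TestGenGwas:
    def _setup(self, alpha, n_genes=500, n_markers=20000, n_planted=200):
        cfg = small_config(n_genes=n_genes, n_markers=n_markers, cis_per_gene=30,
                           set_size_range=(5, 15))
        ids = gene_ids(cfg)
        planted = PlantedSet("P", tuple(ids[:n_planted]), enrichment_alpha=alpha)
        _, _, eqtl = gen_genome(cfg)
        gwas = gen_gwas(eqtl, [planted], cfg)
        planted_markers = set(eqtl[eqtl["GENE"].isin(planted.member_genes)]["MARKER"])
        pmap = dict(zip(gwas["MARKER"], gwas["PVALUE"]))
        inside = np.array([pmap[m] for m in planted_markers])
        outside = np.array([p for m, p in pmap.items() if m not in planted_markers])
        return inside, outside

    def test_beta_mean_closed_form(self):
        inside, _ = self._setup(alpha=0.2)
        assert len(inside) >= 5000
        # Beta(0.2, 1) mean = 0.2/1.2; SE ~ sqrt(var/n)
        se = np.sqrt(inside.var() / len(inside))
        assert abs(inside.mean() - 0.2 / 1.2) < 4 * se + 1e-9

    def test_alpha_one_indistinguishable_from_uniform(self):
        inside, _ = self._setup(alpha=1.0)
        assert stats.kstest(inside, "uniform").pvalue > 0.01

    def test_beta_goodness_of_fit(self):
        inside, outside = self._setup(alpha=0.3)
        assert stats.kstest(inside, stats.beta(0.3, 1).cdf).pvalue > 0.001
        assert stats.kstest(outside, "uniform").pvalue > 0.001

    def test_no_planted_all_uniform(self):
        cfg = small_config(n_genes=200, n_markers=10000, cis_per_gene=10)
        _, _, eqtl = gen_genome(cfg)
        gwas = gen_gwas(eqtl, [], cfg)
        assert stats.kstest(gwas["PVALUE"], "uniform").pvalue > 0.001

    def test_smallest_alpha_wins_on_shared_marker(self):
        cfg = small_config(n_genes=20, n_markers=100, cis_per_gene=2)
        ids = gene_ids(cfg)
        _, _, eqtl = gen_genome(cfg)
        strong = PlantedSet("S", (ids[0],), enrichment_alpha=0.1)
        weak = PlantedSet("W", (ids[0],), enrichment_alpha=0.9)
        gwas_both = gen_gwas(eqtl, [weak, strong], cfg)
        gwas_strong = gen_gwas(eqtl, [strong], cfg)
        assert gwas_both.equals(gwas_strong)

    def test_unknown_planted_gene_listed(self):
        cfg = small_config()
        _, _, eqtl = gen_genome(cfg)
        ghost = PlantedSet("G", ("GHOST1",), enrichment_alpha=0.5)
        with pytest.raises(ConfigError, match="GHOST1"):
            gen_gwas(eqtl, [ghost], cfg)


class TestGenGeneSets:
    def test_count_includes_planted_and_engineered(self):
        cfg = small_config(n_genes=200, n_sets=30,
                           overlap_pairs=((40, 40, 0.5),),
                           planted_sets=(PlantedSet(
                               "P", tuple(gene_ids(small_config(n_genes=200))[:10])),))
        coll = gen_gene_sets(cfg)
        assert len(coll) == 30 + 1 + 2

    def test_engineered_overlap_exact(self):
        cfg = small_config(n_genes=200, n_sets=0, overlap_pairs=((40, 40, 0.5),))
        coll = gen_gene_sets(cfg)
        assert len(coll["OVL01A"] & coll["OVL01B"]) == 20
        assert len(coll["OVL01A"]) == 40 and len(coll["OVL01B"]) == 40

    def test_bad_overlap_fraction(self):
        cfg = small_config(n_genes=200, overlap_pairs=((10, 10, 1.2),))
        with pytest.raises(ConfigError, match="fraction"):
            gen_gene_sets(cfg)

    def test_identical_gmt_serialization(self, tmp_path):
        cfg = small_config(n_genes=200, n_sets=10)
        write_gmt(gen_gene_sets(cfg), tmp_path / "a.gmt")
        write_gmt(gen_gene_sets(cfg), tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_decoys_exclude_planted(self):
        ids = gene_ids(small_config(n_genes=100))
        planted = PlantedSet("P", tuple(ids[:50]))
        cfg = small_config(n_genes=100, n_sets=20, planted_sets=(planted,),
                           decoys_exclude_planted=True, set_size_range=(5, 10))
        coll = gen_gene_sets(cfg)
        planted_genes = set(planted.member_genes)
        for sid in coll:
            if sid.startswith("RAND"):
                assert not (coll[sid] & planted_genes)


class TestGenNetwork:
    def _planted_cfg(self, fraction=0.6, out_degree=10, n_genes=300):
        ids = gene_ids(small_config(n_genes=n_genes))
        planted = PlantedSet("P", tuple(ids[:40]), planted_kd=ids[0])
        return SimConfig(n_genes=n_genes, n_markers=500, seed=5,
                         planted_sets=(planted,), kd_out_degree=out_degree,
                         kd_member_fraction=fraction), planted

    def test_acyclic(self):
        cfg, _ = self._planted_cfg()
        edges = gen_network(cfg)
        g = nx.DiGraph(list(zip(edges["SRC"], edges["DST"])))
        assert nx.is_directed_acyclic_graph(g)

    def test_planted_kd_out_fraction(self):
        cfg, planted = self._planted_cfg(fraction=0.6, out_degree=10)
        edges = gen_network(cfg)
        out = set(edges[edges["SRC"] == planted.planted_kd]["DST"])
        members = set(planted.member_genes)
        assert len(out) >= 10
        assert len(out & members) / len(out) >= 0.6

    def test_deterministic_edge_list(self):
        cfg, _ = self._planted_cfg()
        assert gen_network(cfg).to_csv() == gen_network(cfg).to_csv()

    def test_infeasible_fraction_errors(self):
        ids = gene_ids(small_config(n_genes=300))
        planted = PlantedSet("P", tuple(ids[:3]), planted_kd=ids[0])
        cfg = SimConfig(n_genes=300, n_markers=500, planted_sets=(planted,),
                        kd_out_degree=20, kd_member_fraction=0.9)
        with pytest.raises(ConfigError, match="too small"):
            gen_network(cfg)


class TestGenExpressionTrait:
    def test_high_r_recovered(self):
        expr, trait = gen_expression_trait(["kd"], 0.99, 500, seed=1)
        r = np.corrcoef(expr.loc["kd"], trait)[0, 1]
        assert 0.95 <= r <= 1.0

    def test_null_type_one_error(self):
        n_sig = 0
        reps = 300
        for seed in range(reps):
            expr, trait = gen_expression_trait(["kd"], 0.0, 30, seed=seed,
                                               other_genes=["x"])
            r, p = stats.pearsonr(expr.loc["x"], trait)
            n_sig += p < 0.05
        assert 0.02 <= n_sig / reps <= 0.09

    def test_zero_noise_exact(self):
        expr, trait = gen_expression_trait(["kd"], 0.5, 100, seed=3, noise_sd=0.0)
        r = np.corrcoef(expr.loc["kd"], trait)[0, 1]
        assert r == pytest.approx(1.0)

    def test_r_bounds(self):
        with pytest.raises(ConfigError, match="r_target"):
            gen_expression_trait(["kd"], 1.0, 100, seed=0)

    def test_infeasible_multi_kd(self):
        with pytest.raises(ConfigError, match="infeasible"):
            gen_expression_trait(["k1", "k2", "k3", "k4"], 0.9, 100, seed=0)

    def test_min_samples(self):
        with pytest.raises(ConfigError, match="n_samples"):
            gen_expression_trait(["kd"], 0.5, 3, seed=0)


class TestGenSpeciesPair:
    def _pair(self, seed=0):
        plan = SharePlan(
            shared=(PlannedSet("SH1", 30, 0.2, kd=True), PlannedSet("SH2", 25)),
            specific_a=(PlannedSet("SPA", 20),),
            specific_b=(PlannedSet("SPB", 20),),
        )
        cfg_a = SimConfig(n_genes=300, n_markers=1000, seed=seed, n_sets=5,
                          species_tag="human")
        cfg_b = SimConfig(n_genes=300, n_markers=1000, seed=seed + 1, n_sets=5,
                          species_tag="mouse")
        return gen_species_pair(cfg_a, cfg_b, plan)

    def test_shared_sets_ortholog_identical(self):
        pair = self._pair()
        by_id_a = {p.set_id: p for p in pair.species_a.config.planted_sets}
        by_id_b = {p.set_id: p for p in pair.species_b.config.planted_sets}
        a_to_b = dict(zip(pair.ortholog_table["GENE_A"], pair.ortholog_table["GENE_B"]))
        for sid in ("SH1", "SH2"):
            translated = {a_to_b[g] for g in by_id_a[sid].member_genes}
            assert translated == set(by_id_b[sid].member_genes)

    def test_specific_sets_disjoint_across_species(self):
        pair = self._pair()
        a_to_b = dict(zip(pair.ortholog_table["GENE_A"], pair.ortholog_table["GENE_B"]))
        spa = next(p for p in pair.species_a.config.planted_sets if p.set_id == "SPA")
        spb = next(p for p in pair.species_b.config.planted_sets if p.set_id == "SPB")
        assert not ({a_to_b[g] for g in spa.member_genes} & set(spb.member_genes))

    def test_truth_lists_plan_ids(self):
        pair = self._pair()
        assert pair.truth["shared"] == ["SH1", "SH2"]
        assert pair.truth["specific_a"] == ["SPA"]
        assert pair.truth["specific_b"] == ["SPB"]

    def test_id_collision_errors(self):
        cfg = SimConfig(n_genes=50, n_markers=100, species_tag="human")
        with pytest.raises(ConfigError, match="collision"):
            gen_species_pair(cfg, cfg, SharePlan())

    def test_truth_ids_resolvable_in_bundles(self):
        pair = self._pair()
        for bundle in (pair.species_a, pair.species_b):
            universe = set(gene_ids(bundle.config))
            for rec in bundle.truth["planted_sets"]:
                assert set(rec["member_genes"]) <= universe
                assert rec["set_id"] in bundle.gene_sets
                if rec["planted_kd"]:
                    assert rec["planted_kd"] in universe


class TestBundleDeterminism:
    def test_bundle_write_hash_stable(self, tmp_path):
        cfg = small_config(n_genes=100, n_markers=400, n_sets=8,
                           trans_fraction=0.2)
        d1 = gen_bundle(cfg).write(tmp_path / "one")
        d2 = gen_bundle(cfg).write(tmp_path / "two")
        files1 = sorted(p.name for p in d1.iterdir())
        files2 = sorted(p.name for p in d2.iterdir())
        assert files1 == files2
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
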