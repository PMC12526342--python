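import numpy as np
import pytest

from aridpop.clones import clone_groups, pairwise_relatedness
from aridpop.io_core import MISSING, write_vcf
from aridpop.qc_filter import FilterConfig, FilterReport, filter_sites, mask_genotypes
from aridpop.synthetic_data import (CloneConfig, GeneConfig, QualityConfig,
                                    QuartetConfig, SimConfig, add_clones,
                                    attach_quality, simulate_annotation,
                                    simulate_coordinates, simulate_quartet,
                                    simulate_structured, write_gff3)


class TestSimulateStructured:
    def test_same_seed_bit_identical_vcf(self, tmp_path):
        for name in ("a.vcf", "b.vcf"):
            cfg = SimConfig(seed=42, n_demes=2, deme_sizes=[6, 6],
                            bn_f=[0.05, 0.05], n_snps=150)
            gm, _ = simulate_structured(cfg)
            write_vcf(gm, tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_beta_variance_matches_model(self):
        cfg = SimConfig(seed=7, n_demes=1, deme_sizes=[5], bn_f=[0.2],
                        n_snps=30_000, freq_range=(0.5, 0.5))
        _, truth = simulate_structured(cfg)
        # ancestral p fixed at 0.5 -> Var(deme freq) should be p(1-p)F = 0.05
        v = truth.deme_freqs[0].var()
        assert v == pytest.approx(0.25 * 0.2, rel=0.05)

    def test_truth_dimensions_consistent(self):
        cfg = SimConfig(seed=8, n_snps=500)
        gm, truth = simulate_structured(cfg)
        assert len(truth.samples) == gm.n_samples == 114
        assert truth.deme_freqs.shape == (4, gm.n_sites)
        assert gm.chromosomes() == [f"PC{i}" for i in range(1, 16)]

    def test_f_zero_demes_are_null(self):
        from aridpop.differentiation import wc_components, weighted_fst
        cfg = SimConfig(seed=9, n_demes=2, deme_sizes=[40, 40],
                        bn_f=[0.0, 0.0], n_snps=5000)
        gm, truth = simulate_structured(cfg)
        fst = weighted_fst(wc_components(gm.dosage, truth.deme_labels(),
                                         (1, 2)))
        assert abs(fst) < 0.01


class TestAddClones:
    def test_noiseless_clones_pi_hat_one(self):
        cfg = SimConfig(seed=10, n_demes=1, deme_sizes=[8], bn_f=[0.0],
                        n_snps=500, clones=CloneConfig(group_sizes=[2]))
        gm, truth = simulate_structured(cfg)
        gm, truth = add_clones(gm, truth, cfg)
        rel = pairwise_relatedness(gm)
        assert rel.lookup("S001", "S001_c1") == pytest.approx(1.0)

    def test_clone_of_clone_single_group_in_truth(self):
        cfg = SimConfig(seed=11, n_demes=1, deme_sizes=[5], bn_f=[0.0],
                        n_snps=200, clones=CloneConfig(group_sizes=[3]))
        gm, truth = simulate_structured(cfg)
        gm, truth = add_clones(gm, truth, cfg)
        assert ["S001", "S001_c1", "S001_c2"] in truth.clone_groups
        assert gm.n_samples == 7

    def test_error_rate_recoverable_at_threshold(self):
        cfg = SimConfig(seed=12, n_demes=1, deme_sizes=[20], bn_f=[0.0],
                        n_snps=2000,
                        clones=CloneConfig(group_sizes=[2, 2],
                                           error_rate=0.005,
                                           missing_rate=0.01))
        gm, truth = simulate_structured(cfg)
        gm, truth = add_clones(gm, truth, cfg)
        found = clone_groups(pairwise_relatedness(gm), 0.95)
        assert sorted(map(sorted, found.groups)) == \
            sorted(map(sorted, truth.clone_groups))


class TestQuartet:
    def test_null_has_no_flow_mask(self):
        cfg = SimConfig(seed=13, quartet=QuartetConfig(n_per_deme=5,
                                                       n_snps=300))
        _, truth, groups = simulate_quartet(cfg)
        assert truth.quartet["site_mask"].sum() == 0
        assert set(groups) == {"P1", "P2", "P3", "O"}

    def test_flow_fraction_and_restriction(self):
        cfg = SimConfig(seed=14, quartet=QuartetConfig(
            n_per_deme=5, n_snps=3000, introgression_f=0.2,
            chromosome="PC5"))
        gm, truth, _ = simulate_quartet(cfg)
        mask = truth.quartet["site_mask"]
        on_pc5 = (gm.sites["chromosome"] == "PC5").to_numpy()
        assert mask.sum() == pytest.approx(0.2 * on_pc5.sum(), abs=1)
        assert not mask[~on_pc5].any()


class TestAnnotationAndQuality:
    def test_gene_count_matches_config(self, tmp_path):
        from aridpop.io_core import read_gff3_genes
        cfg = SimConfig(seed=15, n_chromosomes=3,
                        genes=GeneConfig(n_genes_per_chrom=10))
        genes = simulate_annotation(cfg)
        assert len(genes) == 30
        write_gff3(genes, tmp_path / "g.gff3")
        assert len(read_gff3_genes(tmp_path / "g.gff3")) == 30

    def test_planted_failures_match_filter_ledger(self):
        cfg = SimConfig(seed=16, n_demes=1, deme_sizes=[40], bn_f=[0.0],
                        n_snps=400, freq_range=(0.3, 0.7),
                        quality=QualityConfig(frac_fail_qual=0.05,
                                              frac_fail_missing=0.05,
                                              frac_fail_maf=0.05,
                                              frac_multiallelic=0.05))
        gm, _ = simulate_structured(cfg)
        gm, truth = attach_quality(gm, cfg)
        rep = FilterReport()
        filter_sites(gm, FilterConfig(), rep)
        planted = truth.planted
        assert rep.dropped_qual == len(planted["qual_sites"])
        assert rep.dropped_missingness == len(planted["missing_sites"])
        assert rep.dropped_maf == len(planted["maf_sites"])
        assert rep.dropped_not_biallelic_snp == len(planted["multiallelic_sites"])

    def test_zero_planted_failures_drop_nothing(self):
        cfg = SimConfig(seed=17, n_demes=1, deme_sizes=[40], bn_f=[0.0],
                        n_snps=300, freq_range=(0.3, 0.7))
        gm, _ = simulate_structured(cfg)
        gm, _ = attach_quality(gm, cfg)
        out = filter_sites(mask_genotypes(gm), FilterConfig())
        assert out.n_sites == gm.n_sites

    def test_planted_cell_failures_masked(self):
        cfg = SimConfig(seed=18, n_demes=1, deme_sizes=[20], bn_f=[0.0],
                        n_snps=200,
                        quality=QualityConfig(frac_fail_dp=0.02,
                                              frac_fail_gq=0.02))
        gm, _ = simulate_structured(cfg)
        gm, truth = attach_quality(gm, cfg)
        masked = mask_genotypes(gm)
        r, c = truth.planted["dp_cells"]
        assert (masked.dosage[r, c] == MISSING).all()
        r, c = truth.planted["gq_cells"]
        assert (masked.dosage[r, c] == MISSING).all()


class TestCoordinates:
    def test_collisions_planted(self):
        cfg = SimConfig(seed=19, n_snps=100)
        _, truth = simulate_structured(cfg)
        metas = simulate_coordinates(truth, cfg, n_collisions=3)
        pts = [(m.latitude, m.longitude) for m in metas]
        assert max(pts.count(p) for p in set(pts)) == 3

    def test_zero_jitter_coincident_demes(self):
        cfg = SimConfig(seed=20, n_snps=100)
        _, truth = simulate_structured(cfg)
        metas = simulate_coordinates(truth, cfg, jitter_deg=0.0,
                                     concentrate_last_deme=False)
        demes = truth.samples["deme"].to_numpy()
        for d in np.unique(demes):
            pts = {(m.latitude, m.longitude)
                   for m, dd in zip(metas, demes) if dd == d}
            assert len(pts) == 1

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=21, n_snps=100)
        _, truth = simulate_structured(cfg)
        a = simulate_coordinates(truth, cfg)
        b = simulate_coordinates(truth, cfg)
        assert [(m.latitude, m.longitude) for m in a] == \
            [(m.latitude, m.longitude) for m in b]
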