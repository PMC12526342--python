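import numpy as np
import pandas as pd
import pytest

from aridpop.differentiation import (outliers_and_genes, pairwise_fst,
                                     wc_components, wc_components_site,
                                     weighted_fst, windowed_fst, WindowStat)
from aridpop.io_core import GeneFeature, ValidationError
from aridpop.synthetic_data import SimConfig, simulate_structured

from conftest import make_gm, make_sites


def wc_1984_reference(counts1, counts2):
    """Independent transcription of the two-population diploid estimator:
    direct textbook formulas from genotype counts (n00, n01, n11) per pop."""
    r = 2
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcComponents:
    def test_fixed_difference_theta_one(self):
        dosage = np.array([[0], [0], [2], [2]], dtype=np.int8)
        labels = np.array([1, 1, 2, 2])
        a, b, c = wc_components_site(dosage[:, 0], labels, (1, 2))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_all_heterozygous_hand_algebra(self):
        # both pops all-het at p = 0.5, n = 2 each: a=0, b=-0.25, c=0.5
        dosage = np.array([[1], [1], [1], [1]], dtype=np.int8)
        labels = np.array([1, 1, 2, 2])
        a, b, c = wc_components_site(dosage[:, 0], labels, (1, 2))
        assert (a, b, c) == pytest.approx((0.0, -0.25, 0.5))
        assert a / (a + b + c) == pytest.approx(0.0)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(3, 12, 2)
            g1 = rng.integers(0, 3, n1)
            g2 = rng.integers(0, 3, n2)
            dosage = np.concatenate([g1, g2]).astype(np.int8).reshape(-1, 1)
            labels = np.array([1] * n1 + [2] * n2)
            a, b, c = wc_components_site(dosage[:, 0], labels, (1, 2))
            c1 = [(g1 == k).sum() for k in (0, 1, 2)]
            c2 = [(g2 == k).sum() for k in (0, 1, 2)]
            ra, rb, rc = wc_1984_reference(c1, c2)
            assert (a, b, c) == pytest.approx((ra, rb, rc), abs=1e-12)

    def test_empty_group_unusable(self):
        dosage = np.array([[0], [0], [-1], [-1]], dtype=np.int8)
        labels = np.array([1, 1, 2, 2])
        comps = wc_components(dosage, labels, (1, 2))
        assert not comps.usable[0]


class TestPairwiseFst:
    def test_single_group_is_error(self, two_deme_gm):
        with pytest.raises(ValidationError):
            pairwise_fst(two_deme_gm, np.ones(10))

    def test_matrix_shape_and_symmetry(self):
        cfg = SimConfig(seed=2, n_demes=3, deme_sizes=[15, 15, 15],
                        bn_f=[0.05, 0.05, 0.15], n_snps=2000)
        gm, truth = simulate_structured(cfg)
        mat = pairwise_fst(gm, truth.deme_labels())
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        # the high-drift deme is the most differentiated
        assert mat.loc[1, 3] > mat.loc[1, 2]

    def test_null_split_near_zero(self):
        cfg = SimConfig(seed=4, n_demes=1, deme_sizes=[60], bn_f=[0.0],
                        n_snps=4000)
        gm, _ = simulate_structured(cfg)
        labels = np.array([1] * 30 + [2] * 30)
        fst = weighted_fst(wc_components(gm.dosage, labels, (1, 2)))
        assert abs(fst) < 0.01

    def test_fixed_difference_demes_one_on_noiseless_fixture(self):
        dosage = np.tile(np.array([[0], [0], [0], [2], [2], [2]],
                                  dtype=np.int8), (1, 4))
        labels = np.array([1, 1, 1, 2, 2, 2])
        fst = weighted_fst(wc_components(dosage, labels, (1, 2)))
        assert fst == pytest.approx(1.0, abs=1e-12)


class TestWindowedFst:
    def _comps(self, n_sites, a=0.1, d=1.0):
        from aridpop.differentiation import WcSiteComponents
        return WcSiteComponents(a=np.full(n_sites, a),
                                b=np.full(n_sites, d - a - 0.02),
                                c=np.full(n_sites, 0.02),
                                usable=np.ones(n_sites, dtype=bool))

    def test_single_snp_window_equals_site_ratio(self):
        sites = make_sites(1, start=25_000)
        comps = self._comps(1, a=0.3, d=1.0)
        ws = windowed_fst(comps, sites)
        assert all(w.fst == pytest.approx(0.3) for w in ws)

    def test_snp_at_50kb_in_five_windows(self):
        sites = make_sites(1, start=50_000)
        ws = windowed_fst(self._comps(1), sites)
        assert len(ws) == 5
        assert [w.start for w in ws] == [1, 10_001, 20_001, 30_001, 40_001]

    def test_uniform_components_constant_windows(self):
        sites = make_sites(200, spacing=1000)
        ws = windowed_fst(self._comps(200), sites)
        vals = {round(w.fst, 12) for w in ws}
        assert vals == {round(0.1, 12)}

    def test_window_site_count_matches_interval_scan(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 150, replace=False))
        sites = make_sites(150)
        sites["position"] = pos
        ws = windowed_fst(self._comps(150), sites)
        total = sum(w.n_snps for w in ws)
        brute = sum(
            sum(1 for w in ws if w.start <= p <= w.end) for p in pos)
        assert total == brute


class TestOutliers:
    def _windows(self, fsts):
        return [WindowStat("PC1", 1 + i * 10_000, 50_000 + i * 10_000,
                           f, 1.0, 5) for i, f in enumerate(fsts)]

    def test_single_spike_recovered(self):
        fsts = [0.01] * 99 + [0.5]
        sites = make_sites(1, start=99 * 10_000 + 100)
        out = outliers_and_genes(self._windows(fsts), sites, [], q=0.99)
        assert len(out.windows) == 1 and out.windows[0].fst == 0.5
        assert out.snp_indices.tolist() == [0]

    def test_gene_at_exact_pad_distance_included(self):
        windows = [WindowStat("PC1", 1, 50_000, 0.9, 1.0, 1)] + \
            self._windows([0.01] * 99)
        sites = make_sites(1, start=10_000)
        gene_at_pad = GeneFeature("g1", "PC1", 12_500, 13_000)
        gene_beyond = GeneFeature("g2", "PC1", 12_501, 13_000)
        out = outliers_and_genes(windows, sites, [gene_at_pad, gene_beyond],
                                 q=0.99, pad=2_500)
        assert [g.gene_id for g in out.genes] == ["g1"]

    def test_quantile_monotone(self):
        rng = np.random.default_rng(9)
        windows = self._windows(rng.uniform(0, 1, 200))
        sites = make_sites(0)
        lo = outliers_and_genes(windows, sites, [], q=0.95)
        hi = outliers_and_genes(windows, sites, [], q=0.99)
        assert len(hi.windows) <= len(lo.windows)

    def test_planted_region_genes_recovered(self):
        from aridpop.synthetic_data import GeneConfig, simulate_annotation
        cfg = SimConfig(seed=21, n_demes=2, deme_sizes=[20, 20],
                        bn_f=[0.02, 0.02], n_snps=3000, n_chromosomes=5,
                        chrom_length_bp=2_000_000,
                        outlier_region=("PC3", 500_001, 600_000),
                        genes=GeneConfig(n_genes_per_chrom=90,
                                         gene_length=5_000, gap=15_000))
        gm, truth = simulate_structured(cfg)
        genes = simulate_annotation(cfg)
        comps = wc_components(gm.dosage, truth.deme_labels(), (1, 2))
        ws = windowed_fst(comps, gm.sites)
        out = outliers_and_genes(ws, gm.sites, genes)
        assert all(w.chromosome == "PC3" for w in out.windows)
        pos = gm.sites["position"].to_numpy()
        ch = gm.sites["chromosome"].to_numpy()
        planted = np.flatnonzero(truth.outlier_site_mask)
        expected = {g.gene_id for g in genes for i in planted
                    if g.chromosome == ch[i]
                    and g.start <= pos[i] + 2_500 and g.end >= pos[i] - 2_500}
        got = {g.gene_id for g in out.genes}
        assert expected <= got
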