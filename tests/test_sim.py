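"""Pedigree simulation: map function, founders, gametes, transmission."""

import math

import numpy as np
import pandas as pd
import pytest

from kinchain import kc
from kinchain import sim as sm
from conftest import make_tiny_panel


class TestKosambi:
    def test_zero_distance(self):
        assert sm.kosambi_rc(0.0) == 0.0

    def test_large_distance_asymptote(self):
        assert sm.kosambi_rc(1e6) == pytest.approx(0.5, abs=1e-12)
        assert sm.kosambi_rc(200.0) < 0.5

    def test_ten_centimorgan(self):
        # direct evaluation of the map function: ½·tanh(0.2)
        assert sm.kosambi_rc(10.0) == pytest.approx(0.0986877, abs=1e-7)
        assert sm.kosambi_rc(10.0) == pytest.approx(0.5 * math.tanh(0.2))

    def test_small_distance_linear(self):
        assert sm.kosambi_rc(0.1) == pytest.approx(0.001, rel=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sm.kosambi_rc(-1.0)

    def test_map_view_rc_bounds(self, simulator):
        for gmap in (simulator.aut_map, simulator.x_map):
            assert (gmap.rc >= 0).all() and (gmap.rc <= 0.5).all()


class TestFounders:
    def test_sex_specific_chromosome_content(self, simulator):
        rng = np.random.default_rng(0)
        m = simulator.sample_founder("M", rng)
        f = simulator.sample_founder("F", rng)
        assert m.x.shape[0] == 1 and m.y is not None
        assert f.x.shape[0] == 2 and f.y is None

    def test_degenerate_frequency_forces_homozygosity(self):
        panel, freqs = make_tiny_panel()
        name = panel.autosomal_strs[0].name
        freqs.alleles[name] = np.array([10])
        freqs.freqs[name] = np.array([1.0])
        sim = sm.PedigreeSimulator(panel, freqs)
        rng = np.random.default_rng(1)
        batch = sim.sample_founder_batch("F", 200, rng)
        idx = [l.name for l in panel.autosomal_loci()].index(name)
        assert (batch.aut[:, idx, :] == 10).all()

    def test_snp_heterozygosity_matches_hwe(self):
        panel, freqs = make_tiny_panel()
        name = panel.autosomal_snps[0].name
        freqs.freqs[name] = np.array([0.3, 0.7])
        sim = sm.PedigreeSimulator(panel, freqs)
        rng = np.random.default_rng(2)
        batch = sim.sample_founder_batch("F", 5000, rng)
        idx = [l.name for l in panel.autosomal_loci()].index(name)
        het = (batch.aut[:, idx, 0] != batch.aut[:, idx, 1]).mean()
        assert het == pytest.approx(0.42, abs=0.02)


class TestGametes:
    def test_no_recombination_returns_parental_haplotype(self):
        panel, freqs = make_tiny_panel()
        sim = sm.PedigreeSimulator(panel, freqs, str_mutation_rate=0.0,
                                   snp_mutation_rate=0.0)
        rng = np.random.default_rng(3)
        L = len(sim.aut_map.names)
        diplo = np.stack([np.full((50, L), 1), np.full((50, L), 2)], axis=-1)
        gmap = sm.GeneticMapView(sim.aut_map.names, sim.aut_map.chroms,
                                 sim.aut_map.cm, np.zeros(L - 1))
        g = sim.make_gamete_batch(diplo, gmap, sim.aut_is_str, rng)
        assert set(np.unique(g.min(1) == g.max(1))) == {True}

    def test_free_recombination_halves_phase_concordance(self):
        panel, freqs = make_tiny_panel(n_a_str=2, n_a_snp=1)
        sim = sm.PedigreeSimulator(panel, freqs, str_mutation_rate=0.0,
                                   snp_mutation_rate=0.0)
        rng = np.random.default_rng(4)
        n, L = 10_000, 3
        diplo = np.stack([np.full((n, L), 1), np.full((n, L), 2)], axis=-1)
        gmap = sm.GeneticMapView(sim.aut_map.names, sim.aut_map.chroms,
                                 sim.aut_map.cm, np.full(L - 1, 0.5))
        g = sim.make_gamete_batch(diplo, gmap, sim.aut_is_str, rng)
        concordance = (g[:, 0] == g[:, 1]).mean()
        assert concordance == pytest.approx(0.5, abs=0.02)

    def test_str_mutation_rate(self):
        panel, freqs = make_tiny_panel(n_a_str=2, n_a_snp=1)
        sim = sm.PedigreeSimulator(panel, freqs)
        rng = np.random.default_rng(5)
        n = 100_000
        L = len(sim.aut_map.names)
        diplo = np.full((n, L, 2), 10)
        g = sim.make_gamete_batch(diplo, sim.aut_map, sim.aut_is_str, rng)
        is_str = sim.aut_is_str
        muts = (g[:, is_str] != 10).sum(0)
        sigma = math.sqrt(n * 0.002 * 0.998)
        for count in muts:
            assert abs(count - 200) <= 3 * sigma
        # mutations are ±1 steps
        assert set(np.unique(g[:, is_str])) <= {9, 10, 11}

    def test_male_x_gamete_rejected(self, simulator):
        rng = np.random.default_rng(6)
        male = simulator.sample_founder("M", rng)
        with pytest.raises(ValueError):
            simulator.make_gamete(male, "X", rng)


class TestTransmission:
    def test_father_son_share_y_up_to_mutation(self, simulator):
        rng = np.random.default_rng(7)
        a, b = simulator.simulate_kc_batch("M→M", 500, rng)
        matches = (a.y == b.y).sum(1)
        assert (matches >= 46).mean() >= 0.99

    def test_mtdna_follows_matriline(self, simulator):
        rng = np.random.default_rng(8)
        a, b = simulator.simulate_kc_batch("F→M", 300, rng)
        assert (a.mt == b.mt).all()
        a, b = simulator.simulate_kc_batch("M→F", 300, rng)
        assert (a.mt == b.mt).mean() < 0.1  # founder-pool collisions only

    def test_mendelian_conservation_without_mutation(
            self, mutation_free_simulator):
        # every child allele at every locus exists in a parent
        rng = np.random.default_rng(9)
        parent, child = mutation_free_simulator.simulate_kc_batch(
            "F→F", 200, rng)
        mat = child.aut[..., 1]  # maternal gamete by construction
        in_parent = (mat == parent.aut[..., 0]) | (mat == parent.aut[..., 1])
        assert in_parent.all()

    def test_dataset_shape_determinism_and_sexes(self, simulator):
        kcs = ["M→M", "F←M→F", "MM"]
        t1 = simulator.simulate_dataset(kcs, 50, 123)
        t2 = simulator.simulate_dataset(kcs, 50, 123)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 150
        assert set(t1.columns) >= {"kc", "replicate", "sexes", "a_ibs",
                                   "a_ibs0", "x_ibs", "x_ibs0", "y_ibs",
                                   "m_ibs"}
        assert (t1.loc[t1.kc == "F←M→F", "sexes"] == "FF").all()
        assert t1.loc[t1.kc == "F←M→F", "y_ibs"].isna().all()

    def test_full_sisters_exceed_mother_daughter_x_ibs(self, simulator):
        table = simulator.simulate_dataset(["F←FM→F", "F→F"], 2000, 11)
        means = table.groupby("kc")["x_ibs"].mean()
        assert means["F←FM→F"] > means["F→F"]

    def test_non_canonical_kc_rejected(self, simulator):
        with pytest.raises(kc.KCParseError):
            simulator.simulate_kc_batch("M→F←M", 10,
                                        np.random.default_rng(0))


class TestGenotypeTables:
    def test_tsv_roundtrip(self, tiny_panel, tmp_path):
        panel, freqs = tiny_panel
        sim = sm.PedigreeSimulator(panel, freqs)
        rng = np.random.default_rng(10)
        a, b = sim.simulate_kc_pair("M→F", rng)
        path = tmp_path / "geno.tsv"
        sm.write_genotypes_tsv({"p1": a, "p2": b}, panel, str(path))
        back = sm.read_genotypes_tsv(str(path), panel)
        for name, orig in (("p1", a), ("p2", b)):
            got = back[name]
            assert got.sex == orig.sex
            np.testing.assert_array_equal(got.autosomal, orig.autosomal)
            np.testing.assert_array_equal(got.x, orig.x)
            if orig.y is None:
                assert got.y is None
            else:
                np.testing.assert_array_equal(got.y, orig.y)
        # mtDNA identity is preserved through the variant-string rendering
        assert (back["p1"].mt == back["p2"].mt) == \
            (sm.mt_variant_string(a.mt) == sm.mt_variant_string(b.mt))

    def test_wrong_columns_rejected(self, tiny_panel, tmp_path):
        panel, _ = tiny_panel
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tsex\tnope\n")
        with pytest.raises(ValueError):
            sm.read_genotypes_tsv(str(path), panel)
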