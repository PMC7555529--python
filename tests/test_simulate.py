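import math

import numpy as np
import pandas as pd
import pytest

from molekaryo import (ConstitutionSpec, construct_conceptus, render_array,
                       render_str, simulate_cohort, simulate_gamete,
                       simulate_parents)
from molekaryo.errors import ConfigError
from molekaryo.panel import AUTOSOMES, GeneticMap, LocusPanel
from molekaryo.simulate import (NOISE_FREE, CaseSpec, NoiseModel, _meiosis,
                                default_cohort_specs,
                                maternal_reference_genome)


def flat_panel(n: int, freq, chrom: str = "1") -> LocusPanel:
    """Single-chromosome panel with constant population frequency."""
    return LocusPanel(pd.DataFrame({
        "locus_id": [f"L{i}" for i in range(n)],
        "chrom": chrom,
        "position": np.arange(1, n + 1) * 1000,
        "pop_b_freq": freq,
    }))


class TestSimulateParents:
    def test_degenerate_frequency_zero_gives_all_A(self):
        panel = flat_panel(100, 0.0)
        parents = simulate_parents(panel, seed=1)
        assert not parents.father_auto["1"].any()
        assert not parents.mother_auto["1"].any()

    def test_heterozygosity_matches_binomial_oracle(self):
        # p(het) = 2 f (1-f) = 0.5 at f = 0.5; binomial SE = sqrt(.25/n)
        n = 10_000
        parents = simulate_parents(flat_panel(n, 0.5), seed=2)
        haps = parents.father_auto["1"]
        het = np.mean(haps[0] != haps[1])
        assert abs(het - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_seed_determinism(self, small_panel, str_panel):
        a = simulate_parents(small_panel, seed=5, str_panel=str_panel)
        b = simulate_parents(small_panel, seed=5, str_panel=str_panel)
        for chrom in AUTOSOMES:
            assert np.array_equal(a.father_auto[chrom], b.father_auto[chrom])
            assert np.array_equal(a.mother_auto[chrom], b.mother_auto[chrom])
        assert a.father_str == b.father_str
        assert np.array_equal(a.mother_mt, b.mother_mt)

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigError):
            LocusPanel(pd.DataFrame(
                columns=["locus_id", "chrom", "position", "pop_b_freq"]))


class TestMeiosis:
    def test_zero_genetic_length_transmits_intact_haplotype(self):
        rng = np.random.default_rng(0)
        haps = rng.random((2, 200)) < 0.5
        gpos = np.linspace(0, 1, 200)
        gam = _meiosis(haps, gpos, 0.0, np.random.default_rng(1))
        assert (np.array_equal(gam.alleles, haps[0])
                or np.array_equal(gam.alleles, haps[1]))
        assert len(set(gam.source)) == 1

    def test_crossover_count_matches_poisson_oracle(self):
        # observed haplotype switches estimate the Poisson(1) crossover count
        n_meioses, n_loci = 4000, 400
        rng = np.random.default_rng(3)
        haps = np.zeros((2, n_loci), dtype=bool)
        gpos = np.linspace(0.001, 0.999, n_loci)
        switches = [int(np.sum(np.diff(_meiosis(haps, gpos, 1.0, rng).source) != 0))
                    for _ in range(n_meioses)]
        se = math.sqrt(1.0 / n_meioses)  # Poisson variance = mean = 1
        assert abs(np.mean(switches) - 1.0) < 3 * se + 0.01

    def test_two_sperm_share_haplotype_half_the_time(self, genetic_map):
        # independent meioses pick the same parental homolog with p = 1/2;
        # the dispermic mole's segmental homozygosity rests on this symmetry
        panel = flat_panel(50, 0.5)
        gmap = GeneticMap({"1": 1.0})
        same = []
        rng = np.random.default_rng(4)
        haps = {"1": (np.random.default_rng(5).random((2, 50)) < 0.5)}
        for _ in range(1000):
            g1 = simulate_gamete(haps, panel, gmap, rng)["1"]
            g2 = simulate_gamete(haps, panel, gmap, rng)["1"]
            same.append(np.mean(g1.source == g2.source))
        assert abs(np.mean(same) - 0.5) < 0.04

    def test_single_haplotype_rejected(self):
        with pytest.raises(ConfigError):
            _meiosis(np.zeros((1, 10), dtype=bool), np.linspace(0, 1, 10),
                     1.0, np.random.default_rng(0))


class TestConstructConceptus:
    def test_monospermic_is_fully_homozygous(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("monospermic_CHM", sex="XX"), parents, seed=7)
        for chrom in AUTOSOMES:
            assert genome.n_het_loci(chrom) == 0
        assert genome.copy_number("X") == 2
        assert np.array_equal(genome.x[0].alleles, genome.x[1].alleles)

    def test_double_trisomy_with_biparental_disomy(self, parents):
        # 48,XX,+7,+11 with maternal extras and a biparental chromosome 4
        spec = ConstitutionSpec(
            "dispermic_CHM", sex="XX",
            extra_chromosomes=(("7", "maternal"), ("11", "maternal")),
            biparental_disomies=("4",))
        genome = construct_conceptus(spec, parents, seed=8)
        for chrom in ("7", "11"):
            assert genome.copy_number(chrom) == 3
            assert genome.origins(chrom).count("maternal") == 1
        assert genome.copy_number("4") == 2
        assert sorted(genome.origins("4")) == ["maternal", "paternal"]
        for chrom in set(AUTOSOMES) - {"7", "11", "4"}:
            assert genome.origins(chrom) == ["paternal", "paternal"]

    def test_biparental_diploid_tags(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("biparental_diploid", sex="XY"), parents, seed=9)
        for chrom in AUTOSOMES:
            assert sorted(genome.origins(chrom)) == ["maternal", "paternal"]
        assert genome.copy_number("Y") == 1

    def test_mt_copied_from_mother(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XY"), parents, seed=10)
        assert np.array_equal(genome.mt, parents.mother_mt)

    def test_disomy_in_biparental_mode_rejected(self):
        with pytest.raises(ConfigError):
            ConstitutionSpec("biparental_diploid", sex="XX",
                             biparental_disomies=("4",))

    def test_unrealizable_sex_rejected(self):
        with pytest.raises(ConfigError):
            ConstitutionSpec("monospermic_CHM", sex="XY")
        with pytest.raises(ConfigError):
            ConstitutionSpec("dispermic_CHM", sex="XXX")

    def test_dispermic_segmental_structure(self, parents):
        # noise-free truth: each autosome splits into runs that are either
        # entirely homozygous or father-heterozygous, depending on whether
        # the two sperm carry the same paternal haplotype
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=12)
        for chrom in ("1", "13"):
            h1, h2 = genome.autosomes[chrom]
            same_source = np.asarray(
                parents.father_auto[chrom][0] ==
                parents.father_auto[chrom][1])
            het = h1.alleles != h2.alleles
            # heterozygosity only where father is heterozygous
            assert not np.any(het & same_source)


class TestRenderArray:
    def test_noise_free_disomic_values(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=20)
        sample = render_array(genome, NOISE_FREE, seed=0)
        chrom1 = sample.chrom_data("1")
        h1, h2 = (h.alleles for h in genome.autosomes["1"])
        k = h1.astype(int) + h2.astype(int)
        assert np.allclose(chrom1["baf"].to_numpy(), k / 2)
        assert np.allclose(chrom1["lrr"].to_numpy(), 0.0)
        het = chrom1["gtype"].to_numpy()[k == 1]
        assert (het == "AB").all()

    def test_noise_free_trisomic_values(self, parents):
        att = 0.8
        noise = NoiseModel(baf_sd=0, lrr_sd=0, lrr_attenuation=att, missing_rate=0)
        spec = ConstitutionSpec("dispermic_CHM", sex="XY",
                                extra_chromosomes=(("13", "maternal"),))
        genome = construct_conceptus(spec, parents, seed=21)
        sample = render_array(genome, noise, seed=0)
        tri = sample.chrom_data("13")
        stack = np.stack([h.alleles for h in genome.autosomes["13"]])
        k = stack.sum(axis=0)
        assert np.allclose(tri["baf"].to_numpy(), np.round(k / 3, 4))
        assert np.allclose(tri["lrr"].to_numpy(),
                           round(att * math.log2(1.5), 4))
        aab = tri["baf"].to_numpy()[k == 1]
        assert np.allclose(aab, round(1 / 3, 4))

    def test_baf_noise_matches_gaussian_oracle(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("biparental_diploid", sex="XX"), parents, seed=22)
        noise = NoiseModel(baf_sd=0.03, lrr_sd=0.0, missing_rate=0.0)
        sample = render_array(genome, noise, seed=23)
        truth = np.concatenate([
            (genome.autosomes[c][0].alleles.astype(int)
             + genome.autosomes[c][1].alleles.astype(int)) / 2
            for c in AUTOSOMES])
        observed = np.concatenate([
            sample.chrom_data(c)["baf"].to_numpy() for c in AUTOSOMES])
        resid = (observed - truth)[truth == 0.5]  # het band: no clipping
        assert resid.std() == pytest.approx(0.03, rel=0.15)

    def test_missing_rate_produces_no_calls(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=24)
        sample = render_array(genome, NoiseModel(missing_rate=0.05), seed=25)
        auto = sample.data[sample.data["chrom"].isin(AUTOSOMES)]
        rate = np.mean(auto["gtype"].to_numpy() == "NC")
        assert 0.02 < rate < 0.09

    def test_absent_y_renders_no_calls_with_deep_lrr(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=26)
        sample = render_array(genome, NOISE_FREE, seed=0)
        ychrom = sample.chrom_data("Y")
        assert (ychrom["gtype"] == "NC").all()
        assert np.allclose(ychrom["lrr"], -3.0)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ConfigError):
            NoiseModel(baf_sd=-0.1)
        with pytest.raises(ConfigError):
            NoiseModel(missing_rate=1.0)
        with pytest.raises(ConfigError):
            NoiseModel(lrr_attenuation=0.0)


class TestRenderStr:
    def test_monospermic_single_allele_everywhere(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("monospermic_CHM", sex="XX"), parents, seed=30)
        profile = render_str(genome)
        for locus in genome.str_panel.autosomal():
            assert len(profile.alleles[locus.name]) == 1

    def test_dispermic_alleles_match_gamete_truth(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XY"), parents, seed=31)
        profile = render_str(genome)
        for locus in genome.str_panel.autosomal():
            truth = {h.str_alleles[locus.name]
                     for h in genome.autosomes[locus.chrom]}
            assert set(profile.alleles[locus.name]) == truth
        assert profile.alleles["AMEL"] == ("X", "Y")

    def test_biparental_shares_maternal_allele_everywhere(self, parents):
        genome = construct_conceptus(
            ConstitutionSpec("biparental_diploid", sex="XX"), parents, seed=32)
        mole = render_str(genome)
        mother = render_str(maternal_reference_genome(parents))
        for locus in genome.str_panel.autosomal():
            assert set(mole.alleles[locus.name]) & set(mother.alleles[locus.name])


class TestSimulateCohort:
    def test_empty_cohort(self, small_panel):
        assert simulate_cohort([], seed=1, panel=small_panel) == []

    def test_default_cohort_spec_composition(self):
        specs = default_cohort_specs()
        assert len(specs) == 31
        aneuploid = [s for s in specs
                     if s.constitution.extra_chromosomes
                     or len(s.constitution.sex) > 2]
        assert len(aneuploid) == 9
        extras = [o for s in specs for _, o in s.constitution.extra_chromosomes]
        assert extras.count("maternal") == 7
        assert extras.count("paternal") == 2  # plus the XYY's extra Y
        disomies = [c for s in specs for c in s.constitution.biparental_disomies]
        assert len(disomies) == 3
        outcomes = [s.outcome for s in specs]
        assert outcomes.count("GTN") == 7

    def test_seed_determinism_byte_identical(self, small_panel, str_panel, tmp_path):
        from molekaryo import write_final_report

        specs = [CaseSpec("C1", ConstitutionSpec("dispermic_CHM", sex="XY"))]
        out = []
        for run in (1, 2):
            cases = simulate_cohort(specs, seed=99, panel=small_panel,
                                    str_panel=str_panel)
            path = tmp_path / f"run{run}.tsv"
            write_final_report([cases[0].mole_array, cases[0].maternal_array], path)
            out.append(path.read_bytes())
        assert out[0] == out[1]
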