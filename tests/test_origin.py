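import math

import numpy as np
import pandas as pd
import pytest

from molekaryo import (ConstitutionSpec, call_copy_number, call_origin,
                       construct_conceptus, mito_identity, read_final_report,
                       render_array, select_loci_maternal_AA, simulate_parents,
                       top_band_retention)
from molekaryo.errors import DataError
from molekaryo.origin import OriginConfig, origin_calls_for_sample
from molekaryo.panel import AUTOSOMES, LocusPanel
from molekaryo.sample import SnpArraySample
from molekaryo.simulate import (NOISE_FREE, Homolog, NoiseModel,
                                maternal_reference_genome)

TABLE1_SELECTED = {"exm717089", "exm1436659", "exm779139",
                   "exm-rs6929796", "exm1021627", "exm44591"}


@pytest.fixture(scope="module")
def duo(parents):
    """Noise-free duo with one maternal trisomy (13), one paternal trisomy
    (3), and one biparental disomy (6)."""
    spec = ConstitutionSpec(
        "dispermic_CHM", sex="XY",
        extra_chromosomes=(("13", "maternal"), ("3", "paternal")),
        biparental_disomies=("6",))
    genome = construct_conceptus(spec, parents, seed=70)
    mole = render_array(genome, NOISE_FREE, seed=0, sample_id="MOLE")
    mother = render_array(maternal_reference_genome(parents), NOISE_FREE,
                          seed=1, sample_id="BLOOD")
    return genome, mole, mother


class TestSelection:
    def test_worked_example_selects_exactly_six_loci(self, worked_example_path):
        samples = read_final_report(worked_example_path)
        selected = select_loci_maternal_AA(samples["HM_MOLE"], samples["HM_BLOOD"])
        assert selected.selected_ids() == TABLE1_SELECTED

    def test_all_bb_mother_selects_nothing(self, duo):
        genome, mole, mother = duo
        bb = mother.data.copy()
        bb["gtype"] = "BB"
        selected = select_loci_maternal_AA(mole, SnpArraySample("BLOOD", bb))
        assert selected.selected_ids() == set()

    def test_every_selected_locus_has_maternal_AA(self, duo):
        genome, mole, mother = duo
        selected = select_loci_maternal_AA(mole, mother)
        maternal = mother.data.set_index("snp_name")["gtype"]
        for chrom, sub in selected.by_chrom.items():
            assert (maternal.loc[sub["snp_name"]] == "AA").all()

    def test_selected_count_matches_binomial_oracle(self, small_panel, duo):
        # P(mother AA) = (1-f)^2 per locus; total selected ~ sum of Bernoullis
        genome, mole, mother = duo
        selected = select_loci_maternal_AA(mole, mother)
        p = (1.0 - small_panel.table.loc[
            small_panel.table["chrom"].isin(AUTOSOMES), "pop_b_freq"]) ** 2
        n_auto = sum(len(selected.loci(c)) for c in AUTOSOMES)
        mean, sd = p.sum(), math.sqrt((p * (1 - p)).sum())
        assert abs(n_auto - mean) < 2.58 * sd

    def test_mismatched_duo_rejected(self, duo, small_panel):
        genome, mole, mother = duo
        half = mother.data.iloc[: len(mother.data) // 2].reset_index(drop=True)
        with pytest.raises(DataError, match="shares only"):
            select_loci_maternal_AA(mole, SnpArraySample("BLOOD", half))


class TestRetention:
    def test_independent_homolog_self_calibration(self, small_panel):
        # homologs drawn iid from population frequencies: observed top-band
        # fraction must match the analytic expectation, statistic ≈ 1
        rng = np.random.default_rng(71)
        parents = simulate_parents(small_panel, seed=72)
        genome = construct_conceptus(
            ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=73)
        for chrom in AUTOSOMES:
            f = small_panel.freqs(chrom)
            genome.autosomes[chrom] = [
                Homolog(rng.random(f.size) < f, "paternal", i)
                for i in range(2)]
        mole = render_array(genome, NOISE_FREE, seed=2)
        mother = render_array(maternal_reference_genome(parents), NOISE_FREE,
                              seed=3)
        selected = select_loci_maternal_AA(mole, mother)
        num = exp = 0.0
        for chrom in AUTOSOMES:
            r = top_band_retention(selected, chrom, 2, panel=small_panel)
            if r.determined:
                num += r.observed_fraction * r.n_selected
                exp += r.expected_fraction * r.n_selected
        assert num / exp == pytest.approx(1.0, abs=0.15)

    def test_structural_zero_on_maternal_chromosomes(self, duo, small_panel):
        genome, mole, mother = duo
        selected = select_loci_maternal_AA(mole, mother)
        for chrom, cn in (("13", 3), ("6", 2)):
            r = top_band_retention(selected, chrom, cn, panel=small_panel)
            assert r.observed_fraction == 0.0
            assert r.statistic == 0.0

    def test_paternal_chromosomes_retain_top_band(self, duo, small_panel):
        genome, mole, mother = duo
        selected = select_loci_maternal_AA(mole, mother)
        for chrom, cn in (("3", 3), ("1", 2)):
            r = top_band_retention(selected, chrom, cn, panel=small_panel)
            assert r.observed_fraction > 0.0
            assert r.statistic > 0.5

    def test_sparse_selection_undetermined(self, duo, small_panel):
        genome, mole, mother = duo
        selected = select_loci_maternal_AA(
            mole, mother, config=OriginConfig(min_selected=10**6))
        r = top_band_retention(selected, "1", 2, panel=small_panel,
                               config=OriginConfig(min_selected=10**6))
        assert not r.determined and "selected loci" in r.reason

    def test_mirrored_bb_selection_agrees(self, duo, small_panel):
        # diagnostic cross-check: maternal-BB loci lose the BAF≈0 band on
        # maternal-carrying chromosomes, mirroring the primary test
        genome, mole, mother = duo
        sel_bb = select_loci_maternal_AA(mole, mother, genotype="BB")
        lost = top_band_retention(sel_bb, "13", 3, panel=small_panel,
                                  mirrored=True)
        kept = top_band_retention(sel_bb, "3", 3, panel=small_panel,
                                  mirrored=True)
        assert lost.statistic == 0.0
        assert kept.statistic > 0.5


class TestCallOrigin:
    def test_trisomy_origin_and_biparental_disomy(self, duo, small_panel):
        genome, mole, mother = duo
        calls = {c: call_copy_number(mole, c) for c in AUTOSOMES}
        origins = origin_calls_for_sample(mole, mother, calls, panel=small_panel)
        assert origins["13"].extra_origin == "maternal"
        assert origins["3"].extra_origin == "paternal"
        assert origins["6"].biparental_disomy
        assert not origins["1"].maternal_contribution

    def test_ambiguous_copy_number_rejected(self, duo, small_panel):
        genome, mole, mother = duo
        from molekaryo.karyotype import ChromosomeCall
        bad = ChromosomeCall("5", "ambiguous", {}, 0.0, 0.0, 100, False)
        with pytest.raises(DataError, match="ambiguous"):
            call_origin(mole, mother, bad, panel=small_panel)


class TestMitoIdentity:
    def test_duo_identical(self, duo):
        genome, mole, mother = duo
        report = mito_identity([mole, mother])
        assert report.identical("MOLE", "BLOOD")

    def test_single_sample_has_no_informative_loci(self, duo):
        genome, mole, mother = duo
        report = mito_identity([mole])
        assert report.informative_loci == []

    def test_swapped_families_detected(self, small_panel, str_panel):
        # mole of family A against mother of family B: MT mismatch expected
        families = []
        for seed in (80, 81):
            parents = simulate_parents(small_panel, seed=seed, str_panel=str_panel)
            genome = construct_conceptus(
                ConstitutionSpec("dispermic_CHM", sex="XX"), parents, seed=seed + 5)
            families.append((
                render_array(genome, NOISE_FREE, seed=seed, sample_id=f"MOLE{seed}"),
                render_array(maternal_reference_genome(parents), NOISE_FREE,
                             seed=seed + 9, sample_id=f"BLOOD{seed}")))
        (mole_a, blood_a), (mole_b, blood_b) = families
        report = mito_identity([mole_a, blood_a, mole_b, blood_b])
        assert report.identical(mole_a.sample_id, blood_a.sample_id)
        assert report.identical(mole_b.sample_id, blood_b.sample_id)
        assert not report.identical(mole_a.sample_id, blood_b.sample_id)
        assert len(report.informative_loci) > 0

    def test_no_mt_loci_rejected(self, duo):
        genome, mole, mother = duo
        stripped = SnpArraySample(
            "S", mole.data[mole.data["chrom"] != "MT"].reset_index(drop=True))
        with pytest.raises(DataError, match="MT"):
            mito_identity([stripped, mother])
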