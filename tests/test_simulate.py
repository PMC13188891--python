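import numpy as np
import pytest

from btmap._rng import derive_rng
from btmap.dominance import chi_square_1to1
from btmap.exceptions import (
    EmptyPopulationError,
    InvalidParameterError,
    SelectionModelError,
)
from btmap.genome import build_genome_map
from btmap.simulate import (
    BC1,
    BC2,
    DOMINANCE,
    CrossDesign,
    SelectionModel,
    apply_selection,
    f1_individual,
    founder_individual,
    fragment_profile,
    make_backcross,
    simulate_amplicon_counts,
    simulate_dominance_survivor_counts,
    simulate_expression_counts,
    simulate_gamete,
    simulate_pool_counts,
)


class TestGametes:
    @pytest.mark.parametrize("sex", ["female", "male"])
    def test_homozygous_parent_transmits_uniform_gamete(self, tiny_gmap, tiny_locus, sex):
        parent = founder_individual(tiny_gmap, "R", sex, tiny_locus)
        gamete = simulate_gamete(parent, tiny_gmap, derive_rng(0))
        for chrom in tiny_gmap.labels:
            assert gamete[chrom].all()

    def test_female_meiosis_is_achiasmatic(self, tiny_gmap, tiny_locus):
        """Every chromosome of a female F1 gamete is all-R or all-S: no recombinants."""
        parent = f1_individual(tiny_gmap, "female", tiny_locus)
        rng = derive_rng(1)
        for _ in range(200):
            gamete = simulate_gamete(parent, tiny_gmap, rng)
            for chrom in tiny_gmap.labels:
                assert gamete[chrom].min() == gamete[chrom].max()

    def test_male_crossover_count_matches_poisson_mean(self):
        """50 cM chromosome: mean switches over 10,000 male gametes ~ 0.5 Morgans."""
        gmap = build_genome_map(1, 1_000_000, 50.0, 10_000)  # 100 markers
        parent = f1_individual(gmap, "male", ("chr1", 500_000))
        rng = derive_rng(2)
        switches = 0
        n = 10_000
        for _ in range(n):
            g = simulate_gamete(parent, gmap, rng)["chr1"]
            switches += int(np.count_nonzero(np.diff(g.astype(np.int8))))
        mean = switches / n
        se = np.sqrt(0.5 / n)
        assert abs(mean - 0.5) < 3 * se + 0.01  # small deficit: co-interval double crossovers


class TestBackcross:
    def test_bc1_segregates_1to1_and_is_uniformly_r1r1(self, tiny_gmap, tiny_locus):
        pop = make_backcross(BC1, tiny_gmap, 2000, seed=3, r2_locus=tiny_locus)
        counts = pop.r2_genotype_counts()
        assert counts["R2R2"] == 0
        frac_ss = counts["S2S2"] / len(pop)
        assert abs(frac_ss - 0.5) < 4 * np.sqrt(0.25 / 2000)
        assert all(ind.r1_genotype == "R1R1" for ind in pop.individuals)

    def test_dominance_backcross_segregates_both_loci(self, tiny_gmap, tiny_locus):
        pop = make_backcross(DOMINANCE, tiny_gmap, 2000, seed=4, r2_locus=tiny_locus)
        r2 = pop.r2_genotype_counts()
        assert r2["S2S2"] == 0  # recurrent parent is the resistant strain
        assert abs(r2["R2R2"] / len(pop) - 0.5) < 4 * np.sqrt(0.25 / 2000)
        r1 = pop.r1_genotype_counts()
        assert abs(r1["R1S1"] / len(pop) - 0.5) < 4 * np.sqrt(0.25 / 2000)

    def test_empty_cross_allowed(self, tiny_gmap, tiny_locus):
        pop = make_backcross(BC1, tiny_gmap, 0, seed=5, r2_locus=tiny_locus)
        assert len(pop) == 0

    def test_unknown_design_rejected(self):
        with pytest.raises(InvalidParameterError):
            CrossDesign(name="BC3_imaginary")

    def test_segregation_chi_square_rejects_at_nominal_rate(self, tiny_gmap, tiny_locus):
        """1:1 chi-square on unselected backcrosses rejects ~5% of seeds."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            pop = make_backcross(BC1, tiny_gmap, 200, seed=1000 + rep, r2_locus=tiny_locus)
            c = pop.r2_genotype_counts()
            _, p = chi_square_1to1(c["S2S2"], c["R2S2"])
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.11


class TestSelection:
    def test_complete_selection_leaves_only_heterozygotes(self, bc1_pop):
        survivors = apply_selection(bc1_pop, SelectionModel.against_s2s2(), seed=6)
        counts = survivors.r2_genotype_counts()
        assert counts["S2S2"] == 0 and counts["R2S2"] == len(survivors) > 0
        assert survivors.selected_flag

    def test_all_ones_model_is_identity_on_membership(self, bc1_pop):
        survivors = apply_selection(bc1_pop, SelectionModel.neutral(), seed=7)
        assert survivors.individuals == bc1_pop.individuals

    def test_recessive_model_kills_every_heterozygote(self, tiny_gmap, tiny_locus):
        pop = make_backcross(DOMINANCE, tiny_gmap, 500, seed=8, r2_locus=tiny_locus)
        survivors = apply_selection(
            pop, SelectionModel.dominance_dose(w_het=0.0), seed=9
        )
        assert survivors.r2_genotype_counts()["R2S2"] == 0
        assert survivors.r1_genotype_counts()["R1S1"] == 0

    def test_uncovered_genotype_raises(self, bc1_pop):
        model = SelectionModel(survival={("R1R1", "S2S2"): 0.5})
        with pytest.raises(SelectionModelError):
            apply_selection(bc1_pop, model, seed=10)

    def test_survival_probability_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            SelectionModel(survival={("R1R1", "S2S2"): 1.5})


class TestPoolSequencing:
    def test_expected_allele_depth_at_known_frequency(self, bc1_pop):
        df = simulate_pool_counts(bc1_pop, mean_depth=1000, error_rate=0.0, seed=11)
        assert set(df.columns) == {"chrom", "pos", "depth_R", "depth_S"}
        af = df["depth_R"] / (df["depth_R"] + df["depth_S"])
        assert abs(af.mean() - 0.25) < 0.05

    def test_monomorphic_susceptible_pool_yields_zero_resistant_depth(
        self, tiny_gmap, tiny_locus
    ):
        from btmap.simulate import Population

        inds = [founder_individual(tiny_gmap, "S", "female", tiny_locus) for _ in range(5)]
        pop = Population(inds, CrossDesign(BC1), tiny_gmap)
        df = simulate_pool_counts(pop, mean_depth=500, error_rate=0.0, seed=12)
        assert (df["depth_R"] == 0).all()

    def test_empty_population_rejected(self, tiny_gmap, tiny_locus):
        from btmap.simulate import Population

        pop = Population([], CrossDesign(BC1), tiny_gmap)
        with pytest.raises(EmptyPopulationError):
            simulate_pool_counts(pop, seed=13)

    def test_error_free_sequencing_is_unbiased(self, tiny_gmap, tiny_locus):
        """E[AF] equals the true pool frequency within 4 SE at depth 10,000."""
        pop = make_backcross(BC1, tiny_gmap, 20, seed=14, r2_locus=tiny_locus)
        from btmap.simulate import _pool_frequencies

        truth = _pool_frequencies(pop)
        df = simulate_pool_counts(pop, mean_depth=10_000, error_rate=0.0, seed=15)
        for chrom, group in df.groupby("chrom"):
            f = truth[chrom]
            af = (group["depth_R"] / (group["depth_R"] + group["depth_S"])).to_numpy()
            se = np.sqrt(np.clip(f * (1 - f), 1e-12, None) / 10_000)
            assert np.all(np.abs(af - f) < 4 * se + 1e-9)

    def test_invalid_parameters_rejected(self, bc1_pop):
        with pytest.raises(InvalidParameterError):
            simulate_pool_counts(bc1_pop, mean_depth=0)
        with pytest.raises(InvalidParameterError):
            simulate_pool_counts(bc1_pop, error_rate=0.5)


class TestAmpliconSequencing:
    def test_clean_amplicons_sit_near_pool_frequency(self, bc1_pop, tiny_gmap):
        markers = [("chr1", int(p)) for p in tiny_gmap["chr1"].markers]
        df = simulate_amplicon_counts(
            bc1_pop, markers, mean_reads=38_000, nonspecific_prob=0.0, seed=16
        )
        af = df["depth_R"] / (df["depth_R"] + df["depth_S"])
        assert np.all(np.abs(af - 0.25) < 0.1)
        assert df["amplicon_id"].tolist() == list(range(1, len(markers) + 1))

    def test_contamination_drags_frequency_toward_offtarget_allele(self, bc1_pop, tiny_gmap):
        markers = [("chr1", int(p)) for p in tiny_gmap["chr1"].markers] * 10
        clean = simulate_amplicon_counts(
            bc1_pop, markers, nonspecific_prob=0.0, seed=17
        )
        dirty = simulate_amplicon_counts(
            bc1_pop, markers, nonspecific_prob=1.0, offtarget_allele="S", seed=17
        )
        af_clean = (clean["depth_R"] / (clean["depth_R"] + clean["depth_S"])).mean()
        af_dirty = (dirty["depth_R"] / (dirty["depth_R"] + dirty["depth_S"])).mean()
        # off-target fraction ~ U(0.3, 0.9): mean AF ~ 0.4 * clean AF
        assert af_dirty < 0.6 * af_clean
        dirty_af = dirty["depth_R"] / (dirty["depth_R"] + dirty["depth_S"])
        assert (dirty_af < 0.125).any()  # heavily contaminated ones breach the QC band


class TestExpressionSimulator:
    def test_null_fold_changes_center_on_equal_expression(self):
        table = simulate_expression_counts(
            n_genes=30, base_means=2000.0, fold_changes=1.0, dispersion=0.05,
            n_reps_per_strain=6, gene_lengths=1500, seed=18,
        )
        s1 = table.counts.iloc[:, :6].mean(axis=1)
        s2 = table.counts.iloc[:, 6:].mean(axis=1)
        assert abs((s2 / s1).mean() - 1.0) < 0.1

    def test_two_replicates_and_large_dispersion_do_not_crash(self):
        table = simulate_expression_counts(
            n_genes=5, base_means=50.0, fold_changes=1.0, dispersion=5.0,
            n_reps_per_strain=2, gene_lengths=1000, seed=19,
        )
        assert table.counts.shape == (5, 4)
        assert (table.counts.values >= 0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(base_means=0.0),
            dict(dispersion=0.0),
            dict(n_reps_per_strain=1),
            dict(gene_lengths=0),
            dict(fold_changes=-1.0),
        ],
    )
    def test_invalid_generator_parameters_rejected(self, kwargs):
        base = dict(n_genes=3, base_means=100.0, fold_changes=1.0, dispersion=0.1,
                    n_reps_per_strain=3, gene_lengths=1000, seed=0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            simulate_expression_counts(**base)


def test_fragment_profiles_follow_genotypes(tiny_gmap, tiny_locus):
    pop = make_backcross(DOMINANCE, tiny_gmap, 50, seed=20, r2_locus=tiny_locus)
    for ind in pop.individuals:
        apn = fragment_profile(ind, "APN1", tiny_gmap)
        expected = {"R2R2": {327}, "R2S2": {327, 234}}[ind.r2_genotype(tiny_gmap)]
        assert apn == expected
        abc = fragment_profile(ind, "ABCC2", tiny_gmap)
        assert abc == ({102} if ind.r1_genotype == "R1R1" else {102, 120})


def test_count_level_dominance_simulator_matches_expectation():
    het, hom = simulate_dominance_survivor_counts(10_000, w_het=0.5, seed=21)
    assert abs(hom - 5000) < 4 * np.sqrt(2500)
    assert abs(het - 2500) < 4 * np.sqrt(10_000 * 0.25)
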