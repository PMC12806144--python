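import numpy as np
import pytest

from crefkit.pwm import scan_sequence
from crefkit.saltation import rotation_angle
from crefkit.decomposition import svd_modules
from crefkit.synthetic import (
    CapacityError,
    SaltationScenario,
    SyntheticError,
    gen_cref,
    gen_gene_sets,
    gen_promoter_fixture,
    gen_repeat_library,
    gen_species_pair,
    make_planted_model,
    random_pwm_library,
    saltation_scenario,
)


class TestPlantedModel:
    def test_spectrum_must_strictly_decrease(self):
        model = make_planted_model(n_genes=60, n_motifs=30, n_levels=2,
                                   gene_block=12, motif_block=6)
        with pytest.raises(SyntheticError, match="decreasing"):
            type(model)(
                n_genes=model.n_genes,
                n_motifs=model.n_motifs,
                spectrum=np.array([5.0, 6.0, 1.0]),
                gene_factors=model.gene_factors,
                motif_factors=model.motif_factors,
            )

    def test_factors_are_orthonormal(self):
        model = make_planted_model(n_genes=120, n_motifs=60, n_levels=3,
                                   gene_block=30, motif_block=12)
        for F in (model.gene_factors, model.motif_factors):
            gram = F.T @ F
            assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-10

    def test_signal_is_entrywise_nonnegative(self, planted_sim):
        assert planted_sim.low_rank.min() >= 0

    def test_non_orthonormal_factors_rejected(self):
        from crefkit.synthetic import PlantedModel

        with pytest.raises(SyntheticError, match="orthonormal"):
            PlantedModel(
                n_genes=4, n_motifs=4,
                spectrum=np.array([3.0, 1.0]),
                gene_factors=np.ones((4, 2)),
                motif_factors=np.eye(4)[:, :2],
            )


class TestGenCref:
    def test_clean_matrix_has_planted_spectrum(self, planted_sim):
        sv = np.linalg.svd(planted_sim.raw, compute_uv=False)
        s = planted_sim.model.spectrum
        assert np.max(np.abs(sv[: s.size] - s) / s) <= 1e-6
        assert np.max(np.abs(sv[s.size :])) < 1e-8 * s[0]

    def test_counts_are_nonnegative_integers(self, corrupted_sim):
        counts = corrupted_sim.cref.counts
        assert counts.dtype == np.int64
        assert counts.min() >= 0

    def test_outlier_count_is_exact(self, corrupted_sim):
        g, m = corrupted_sim.cref.counts.shape
        expected = int(np.ceil(0.02 * g * m))
        assert corrupted_sim.outlier_mask.sum() == expected == 720
        assert np.count_nonzero(corrupted_sim.sparse_true) == expected

    def test_ground_truth_rank(self, corrupted_sim):
        assert np.linalg.matrix_rank(corrupted_sim.low_rank) == 6

    def test_same_seed_is_bit_identical(self):
        kwargs = dict(n_genes=90, n_motifs=30, n_levels=2, gene_block=15,
                      motif_block=6, depth=20, corruption_fraction=0.05,
                      noise_model="poisson", seed=77)
        a = gen_cref(make_planted_model(**kwargs))
        b = gen_cref(make_planted_model(**kwargs))
        np.testing.assert_array_equal(a.cref.counts, b.cref.counts)
        np.testing.assert_array_equal(a.outlier_mask, b.outlier_mask)

    def test_poisson_noise_centres_on_signal(self):
        model = make_planted_model(n_genes=300, n_motifs=120, n_levels=2,
                                   gene_block=60, motif_block=24, depth=100,
                                   noise_model="poisson", seed=5)
        sim = gen_cref(model)
        resid = sim.cref.counts - sim.low_rank
        # Poisson: mean ~ 0, variance ~ mean count
        assert abs(resid.mean()) < 0.1
        assert 0.8 < resid.var() / sim.low_rank.mean() < 1.2


class TestSpeciesPair:
    def test_zero_rotation_preserves_motif_factors(self):
        sc = saltation_scenario(seed=3, rotation_deg=0.0, n_genes=300,
                                n_motifs=120, depth=50, noise_model="none")
        a, b = gen_species_pair(sc)
        np.testing.assert_allclose(
            a.model.motif_factors, b.model.motif_factors, atol=1e-12
        )

    def test_right_angle_rotation_is_orthogonal(self):
        sc = saltation_scenario(seed=3, rotation_deg=90.0, n_genes=300,
                                n_motifs=120, depth=50, noise_model="none")
        a, b = gen_species_pair(sc)
        k = sc.rotated_level_pair[0]
        assert abs(a.model.motif_factors[:, k] @ b.model.motif_factors[:, k]) < 1e-12

    def test_planted_rotation_recovered_noise_free(self):
        sc = saltation_scenario(seed=4, rotation_deg=40.0, n_genes=300,
                                n_motifs=120, depth=50, noise_model="none")
        a, b = gen_species_pair(sc)
        k = sc.rotated_level_pair[0]
        ma = svd_modules(a.raw, sc.base.n_levels)
        mb = svd_modules(b.raw, sc.base.n_levels)
        angle, oop = rotation_angle(
            ma[k].motif_vector, ma[k + 1].motif_vector, mb[k].motif_vector
        )
        assert angle == pytest.approx(40.0, abs=1e-6)
        assert oop < 1e-10

    def test_gap_is_planted_in_both_spectra(self):
        sc = saltation_scenario(seed=4, gap_fraction=0.02, n_genes=300,
                                n_motifs=120, depth=50, noise_model="none")
        k = sc.rotated_level_pair[0]
        a, b = gen_species_pair(sc)
        for sim in (a, b):
            s = sim.model.spectrum
            assert (s[k] - s[k + 1]) / s[k] == pytest.approx(0.02)

    def test_non_adjacent_pair_rejected(self):
        base = make_planted_model(n_genes=120, n_motifs=60, n_levels=3,
                                  gene_block=30, motif_block=12)
        with pytest.raises(SyntheticError, match="adjacent"):
            SaltationScenario(base=base, rotated_level_pair=(1, 3))

    def test_pair_outside_levels_rejected(self):
        base = make_planted_model(n_genes=120, n_motifs=60, n_levels=3,
                                  gene_block=30, motif_block=12)
        with pytest.raises(SyntheticError, match="outside"):
            SaltationScenario(base=base, rotated_level_pair=(3, 4))


class TestPromoterFixture:
    def test_zero_counts_gives_hit_free_background(self, pwm_lib):
        fix = gen_promoter_fixture({}, pwm_lib, seed=41)
        assert len(fix.sequence) == 1501
        for pwm in pwm_lib:
            assert scan_sequence(pwm, fix.sequence) == 0

    def test_all_planted_counts_recovered(self, pwm_lib):
        wanted = {"M000": 2, "M001": 1, "M005": 3}
        fix = gen_promoter_fixture(wanted, pwm_lib, seed=42)
        for pwm in pwm_lib:
            assert scan_sequence(pwm, fix.sequence) == wanted.get(pwm.id, 0)

    def test_determinism(self, pwm_lib):
        a = gen_promoter_fixture({"M001": 2}, pwm_lib, seed=43)
        b = gen_promoter_fixture({"M001": 2}, pwm_lib, seed=43)
        assert a.sequence == b.sequence
        assert a.planted_sites == b.planted_sites

    def test_overfull_window_raises_capacity_error(self):
        lib = random_pwm_library(n_motifs=1, length=100, seed=2)
        with pytest.raises(CapacityError):
            gen_promoter_fixture({lib.motif_ids[0]: 20}, lib, seed=44)


class TestGeneSets:
    def test_zero_strength_draws_are_uniform(self):
        rng = np.random.default_rng(6)
        loadings = rng.standard_normal(500)
        genes = [f"g{i}" for i in range(500)]
        coll, flags = gen_gene_sets(loadings, genes, n_enriched=200, n_null=0,
                                    strength=0.0, set_size=10, seed=7)
        ranks = np.empty(500)
        ranks[np.argsort(-loadings)] = np.arange(500)
        picked = [ranks[genes.index(g)] for s in coll.sets.values() for g in s]
        # mean rank of uniform draws ~ 249.5 +- ~3.2 at n=2000
        assert abs(np.mean(picked) - 249.5) < 13

    def test_flags_cover_all_sets(self):
        loadings = np.arange(100.0)
        genes = [f"g{i}" for i in range(100)]
        coll, flags = gen_gene_sets(loadings, genes, n_enriched=2, n_null=3,
                                    set_size=5, seed=8)
        assert set(flags) == set(coll.sets)
        assert sorted(set(flags.values())) == ["enriched", "null"]

    def test_set_size_must_be_below_universe(self):
        with pytest.raises(SyntheticError):
            gen_gene_sets(np.arange(10.0), [f"g{i}" for i in range(10)],
                          set_size=10, seed=1)


class TestRepeatLibrary:
    def test_planted_subset_recovered_exactly(self, pwm_lib):
        from crefkit.repeats import find_mpa

        planted = {"M000", "M002", "M005"}
        rep = gen_repeat_library(pwm_lib, planted, seed=51)
        assert find_mpa(pwm_lib, rep.consensi) == planted

    def test_empty_subset_gives_hit_free_consensi(self, pwm_lib):
        from crefkit.repeats import find_mpa

        rep = gen_repeat_library(pwm_lib, set(), seed=52)
        assert find_mpa(pwm_lib, rep.consensi) == set()

    def test_unknown_motif_rejected(self, pwm_lib):
        with pytest.raises(SyntheticError, match="not in library"):
            gen_repeat_library(pwm_lib, {"NOPE"}, seed=53)
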