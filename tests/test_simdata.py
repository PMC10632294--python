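import numpy as np
import pytest

from clonepart import simdata
from clonepart.simdata import (
    ArchitectureConfig,
    FamilyConfig,
    LinkageMapSpec,
    NoiseConfig,
    PhasedGenotype,
    SiteSpec,
    apply_genotype_missingness,
    assign_genetic_values,
    simulate_family,
    simulate_gamete,
    simulate_parent_genotypes,
    simulate_trial,
)
from conftest import SEG_PROBS


class TestLinkageMap:
    def test_default_map_matches_group_structure(self):
        m = simdata.default_linkage_map()
        assert len(m.groups) == 12
        assert m.n_loci == 1630

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            LinkageMapSpec(groups=[], loci=[])
        with pytest.raises(ValueError):
            LinkageMapSpec(groups=[("g", 10.0)], loci=[("g", 12.0, "s1")])
        with pytest.raises(ValueError):
            LinkageMapSpec(groups=[("g", 0.0)], loci=[])


class TestParentGenotypes:
    def test_forced_hetxhet_gives_expected_freq_half(self, small_map):
        parents = simulate_parent_genotypes(small_map, {"AaxAa": 1.0}, seed=1)
        freqs = (parents["mother"].dosage + parents["fatherA"].dosage) / 4.0
        assert np.all(freqs == 0.5)

    def test_class_mix_gives_quarter_half_threequarter_freqs(self, small_map):
        parents = simulate_parent_genotypes(
            small_map, {"AaxAa": 0.4, "Aaxaa": 0.3, "AAxAa": 0.3}, seed=2
        )
        freqs = (parents["mother"].dosage + parents["fatherA"].dosage) / 4.0
        assert set(np.unique(freqs)) <= {0.25, 0.5, 0.75}

    def test_non_segregating_class_rejected(self, small_map):
        with pytest.raises(ValueError, match="non-segregating"):
            simulate_parent_genotypes(small_map, {"AAxAA": 0.5, "AaxAa": 0.5}, seed=3)

    def test_empty_map_rejected(self):
        tiny = LinkageMapSpec(groups=[("g", 1.0)], loci=[])
        with pytest.raises(ValueError, match="empty"):
            simulate_parent_genotypes(tiny, {"AaxAa": 1.0}, seed=4)


class TestGametes:
    def test_haldane_recombination_fraction_at_one_morgan(self):
        # two loci 100 cM apart: Haldane closed form (1 - exp(-2)) / 2 ~ 0.432
        m = LinkageMapSpec(groups=[("g", 100.0)], loci=[("g", 0.0, "a"), ("g", 100.0, "b")])
        parent = PhasedGenotype(np.array([[1, 1], [0, 0]], dtype=np.int8))
        rng = np.random.default_rng(5)
        gametes = np.stack([simulate_gamete(parent, m, rng) for _ in range(12000)])
        rec = (gametes[:, 0] != gametes[:, 1]).mean()
        assert abs(rec - (1 - np.exp(-2)) / 2) < 0.015

    def test_near_zero_length_map_transmits_whole_haplotypes_fairly(self):
        m = LinkageMapSpec(groups=[("g", 1e-9)], loci=[("g", 0.0, "a"), ("g", 0.0, "b")])
        parent = PhasedGenotype(np.array([[1, 1], [0, 0]], dtype=np.int8))
        rng = np.random.default_rng(6)
        gametes = np.stack([simulate_gamete(parent, m, rng) for _ in range(2000)])
        assert np.all(gametes[:, 0] == gametes[:, 1])  # co-located loci co-inherit
        assert abs(gametes[:, 0].mean() - 0.5) < 0.05  # fair haplotype choice

    def test_colocated_loci_always_coinherited(self):
        m = LinkageMapSpec(groups=[("g", 50.0)], loci=[("g", 25.0, "a"), ("g", 25.0, "b")])
        parent = PhasedGenotype(np.array([[1, 0], [0, 1]], dtype=np.int8))
        rng = np.random.default_rng(7)
        for _ in range(200):
            g = simulate_gamete(parent, m, rng)
            assert g[0] + g[1] == 1  # always one or the other haplotype, never mixed


class TestFamilies:
    def test_pure_family_shares_both_parents(self, small_map):
        parents = simulate_parent_genotypes(small_map, SEG_PROBS, seed=8)
        fam = simulate_family(FamilyConfig(n_offspring=50, n_genotyped=10, seed=9), small_map, parents)
        assert np.all(fam.paternity == 0)

    def test_mixture_paternity_counts_binomial(self, small_map):
        parents = simulate_parent_genotypes(small_map, SEG_PROBS, seed=10, n_extra_fathers=1)
        fam = simulate_family(
            FamilyConfig(n_offspring=478, n_genotyped=478, mixture_fraction=0.594, seed=11),
            small_map,
            parents,
        )
        n_a = (fam.paternity == 0).sum()
        # expected 284 with binomial sd ~ 10.7; allow 4 sd
        assert abs(n_a - 0.594 * 478) < 4 * np.sqrt(478 * 0.594 * 0.406)

    def test_mixture_without_second_father_rejected(self, small_map):
        parents = simulate_parent_genotypes(small_map, SEG_PROBS, seed=12)
        with pytest.raises(ValueError, match="second father"):
            simulate_family(FamilyConfig(mixture_fraction=0.6, seed=13), small_map, parents)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            FamilyConfig(mixture_fraction=0.0)
        with pytest.raises(ValueError):
            FamilyConfig(mixture_fraction=1.2)

    def test_heterozygosity_half_at_hetxhet_snps(self, small_map):
        parents = simulate_parent_genotypes(small_map, {"AaxAa": 1.0}, seed=14)
        fam = simulate_family(FamilyConfig(n_offspring=400, n_genotyped=10, seed=15), small_map, parents)
        het = (fam.genotypes.calls == 1).mean(axis=0)
        assert abs(het.mean() - 0.5) < 0.02

    def test_mean_dosage_tracks_expected_offspring_frequency(self, small_map):
        parents = simulate_parent_genotypes(small_map, SEG_PROBS, seed=16)
        fam = simulate_family(FamilyConfig(n_offspring=500, n_genotyped=10, seed=17), small_map, parents)
        expected = 2.0 * (parents["mother"].dosage + parents["fatherA"].dosage) / 4.0
        assert set(np.unique(expected)) <= {0.5, 1.0, 1.5}
        assert np.max(np.abs(fam.genotypes.calls.mean(axis=0) - expected)) < 0.2


class TestGeneticValues:
    def test_variance_targets_hit(self, family200):
        fam, gv = family200
        assert gv.u.var() == pytest.approx(1.0, abs=1e-9)
        assert gv.u_additive.var() / gv.u.var() == pytest.approx(0.75, abs=0.02)

    def test_fully_additive_architecture_has_zero_dominance(self, family200):
        fam, _ = family200
        gv = assign_genetic_values(
            fam.genotypes, ArchitectureConfig(r_a=1.0, n_causal_add=80, n_causal_dom=80), seed=1
        )
        assert np.all(gv.u_dominance == 0)

    def test_degenerate_architectures_rejected(self, family200):
        fam, _ = family200
        with pytest.raises(ValueError):
            assign_genetic_values(fam.genotypes, ArchitectureConfig(n_causal_add=0), seed=1)
        with pytest.raises(ValueError):
            ArchitectureConfig(sigma_u2=0.0)
        with pytest.raises(ValueError):
            ArchitectureConfig(r_a=np.nan)


class TestTrials:
    def test_nugget_only_phenotypic_variance(self):
        site = SiteSpec(name="s", n_blocks=2, master_blocks=((1, 2),), block_grid=(10, 10))
        noise = NoiseConfig(sigma_v2=0.0, sigma_r2=1.3, sigma_s2=0.0, rho_c=0.0, rho_r=0.0)
        trial = simulate_trial(site, np.zeros(90), noise, seed=20)
        y = trial.frame["value"].dropna()
        assert y.var() == pytest.approx(1.3, rel=0.15)

    def test_spatial_lag1_column_correlation(self):
        noise = NoiseConfig(sigma_v2=0.0, sigma_r2=0.0, sigma_s2=1.0, rho_c=0.8, rho_r=0.6)
        rng = np.random.default_rng(21)
        cols, rows = [], []
        for _ in range(20):  # average over fields: one 30x30 draw is too noisy
            field = simdata._spatial_field(30, 30, noise, rng)
            cols.append(np.corrcoef(field[:-1].ravel(), field[1:].ravel())[0, 1])
            rows.append(np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1])
        lag1_col, lag1_row = np.mean(cols), np.mean(rows)
        assert abs(lag1_col - 0.8) < 0.05
        assert abs(lag1_row - 0.6) < 0.05

    def test_spatial_covariance_converges_to_separable_form(self):
        # sample covariance over replicates ~ sigma_s2 * rho_c^|dc| * rho_r^|dr|
        noise = NoiseConfig(sigma_v2=0.0, sigma_r2=0.0, sigma_s2=1.0, rho_c=0.7, rho_r=0.5)
        rng = np.random.default_rng(22)
        reps = np.stack([simdata._spatial_field(8, 8, noise, rng) for _ in range(3000)])
        for (dc, dr) in [(0, 0), (1, 0), (0, 1), (2, 1)]:
            emp = np.mean(reps[:, 0, 0] * reps[:, dc, dr])
            assert emp == pytest.approx(0.7**dc * 0.5**dr, abs=0.06)

    def test_master_blocks_have_unique_plots_and_fillers_missing(self):
        site = SiteSpec(name="s", n_blocks=4, master_blocks=((1, 2), (3, 4)), block_grid=(6, 10))
        trial = simulate_trial(site, np.zeros(50), NoiseConfig(), seed=23)
        f = trial.frame
        assert not f.duplicated(subset=["master_block", "column", "row"]).any()
        fillers = f[f["genotype_id"].isna()]
        assert len(fillers) == 4 * (60 - 50)
        assert fillers["value"].isna().all()
        assert f[f["genotype_id"].notna()].groupby("genotype_id").size().eq(4).all()

    def test_grid_too_small_rejected(self):
        site = SiteSpec(name="s", n_blocks=2, master_blocks=((1, 2),), block_grid=(3, 3))
        with pytest.raises(ValueError, match="grid too small"):
            simulate_trial(site, np.zeros(10), NoiseConfig(), seed=24)

    def test_same_seed_bitwise_reproducible(self, small_map):
        def build():
            parents = simulate_parent_genotypes(small_map, SEG_PROBS, seed=25)
            fam = simulate_family(FamilyConfig(n_offspring=40, n_genotyped=20, seed=26), small_map, parents)
            trial = simulate_trial(
                SiteSpec(name="s", n_blocks=2, master_blocks=((1, 2),), block_grid=(6, 7)),
                np.arange(40, dtype=float),
                NoiseConfig(),
                seed=27,
            )
            return fam, trial

        f1, t1 = build()
        f2, t2 = build()
        assert np.array_equal(f1.genotypes.calls, f2.genotypes.calls)
        assert t1.frame.equals(t2.frame)


class TestMissingness:
    def test_full_call_rate_keeps_everything(self, family200):
        fam, _ = family200
        out = apply_genotype_missingness(fam.genotypes, 1.0, 1.0, seed=30)
        assert np.array_equal(out.calls, fam.genotypes.calls)

    def test_target_mean_call_rate_realized(self, family200):
        fam, _ = family200
        out = apply_genotype_missingness(fam.genotypes, 0.79, 1.0, seed=31)
        assert out.calls.size >= 1e4
        assert (out.calls != simdata.MISSING).mean() == pytest.approx(0.79, abs=0.01)

    def test_posterior_error_matches_argmax_mismatch_rate(self, family200):
        fam, _ = family200
        out = apply_genotype_missingness(fam.genotypes, 1.0, 1.0, posterior_error=0.013, seed=32)
        mismatch = (out.probs.argmax(axis=2) != fam.genotypes.calls).mean()
        assert mismatch == pytest.approx(0.013, abs=0.004)

    def test_invalid_rates_rejected(self, family200):
        fam, _ = family200
        with pytest.raises(ValueError):
            apply_genotype_missingness(fam.genotypes, 1.2, 1.0, seed=33)
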