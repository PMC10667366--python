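"""Simulation engine: genotypes, effects, phenotypes, filters, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mtlgwas.simulate import (
    COV_CS_LT,
    VAR_CS,
    SimulationConfig,
    apply_mac_filter,
    inject_missingness,
    simulate_dataset,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotypes,
)


def small_config(**kw):
    defaults = dict(n_individuals=300, n_variants=500, n_causal=20)
    defaults.update(kw)
    return dataclasses.replace(SimulationConfig(), **defaults)


class TestGenotypes:
    def test_minimum_frequency_offset(self):
        geno = simulate_genotypes(small_config(n_variants=5000), np.random.default_rng(0))
        assert geno.variants["freq"].min() >= 0.01

    def test_mean_frequency_matches_beta_moments(self):
        geno = simulate_genotypes(
            small_config(n_variants=20000), np.random.default_rng(1)
        )
        # E[Beta(2,10)] + 0.01 = 1/6 + 0.01
        assert abs(geno.variants["freq"].mean() - (1 / 6 + 0.01)) < 0.004

    def test_dosage_mean_tracks_2f(self):
        geno = simulate_genotypes(
            small_config(n_individuals=2000, n_variants=300), np.random.default_rng(2)
        )
        mean_dosage = geno.dosages.astype(float).mean(axis=1)
        freq = geno.variants["freq"].to_numpy()
        resid = mean_dosage - 2 * freq
        assert np.abs(resid).max() < 6 * np.sqrt(2 * 0.35 * 0.65 / 2000) + 0.05

    def test_hardy_weinberg_goodness_of_fit(self):
        from scipy import stats

        geno = simulate_genotypes(
            small_config(n_individuals=3000, n_variants=400), np.random.default_rng(3)
        )
        freq = geno.variants["freq"].to_numpy()
        pvals = []
        for r in range(geno.n_variants):
            counts = np.bincount(geno.dosages[r].astype(int), minlength=3)
            f = freq[r]
            expect = 3000 * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            keep = expect > 1e-12
            chi2 = ((counts[keep] - expect[keep]) ** 2 / expect[keep]).sum()
            pvals.append(stats.chi2.sf(chi2, 2))
        assert np.mean(np.array(pvals) > 0.05) >= 0.93


class TestEffects:
    def test_causal_count_and_background(self):
        cfg = small_config(n_variants=1000, n_causal=50)
        truth = simulate_effects(cfg, np.random.default_rng(4))
        assert truth["causal"].sum() == 50
        causal_beta = truth.loc[truth.causal, "beta_trait1"]
        null_beta = truth.loc[~truth.causal, "beta_trait1"]
        assert abs(causal_beta.mean() - 10.0) < 3.0
        assert abs(null_beta.mean() - 0.01) < 0.05

    @pytest.mark.parametrize("lt", [1.0, 100.0])
    def test_lt_attenuation_scaling(self, lt):
        cfg = small_config(n_variants=20000, lt_attenuation=lt)
        truth = simulate_effects(cfg, np.random.default_rng(5))
        causal = truth[truth.causal]
        mu = cfg.effect_mean()
        assert abs(mu[3] - 10.0 / lt) < 1e-12
        delta = truth.loc[~truth.causal, "delta_trait1"]
        assert abs(delta.var() * 1000 - 10.0 / lt) < 0.5 * 10.0 / lt

    def test_causal_covariance_matches_printed_matrices(self):
        cfg = small_config(n_variants=10000, n_causal=10000)
        truth = simulate_effects(cfg, np.random.default_rng(6))
        beta = truth[[f"beta_trait{k}" for k in (1, 2, 3)]].to_numpy()
        delta = truth[[f"delta_trait{k}" for k in (1, 2, 3)]].to_numpy()
        assert np.abs(np.cov(beta.T) - VAR_CS).max() < 1.0
        assert np.abs(np.cov(beta.T, delta.T)[:3, 3:] - COV_CS_LT).max() < 1.0

    def test_non_pd_assembly_rejected(self):
        bad = dataclasses.replace(
            SimulationConfig(), cov_cs_lt=np.full((3, 3), 50.0), lt_attenuation=100.0
        )
        with pytest.raises(ValueError, match="positive definite"):
            bad.effect_cov()


class TestPhenotypes:
    def test_zero_effects_reduce_to_fixed_part(self):
        cfg = small_config(n_individuals=50, n_variants=20, n_causal=0)
        rng = np.random.default_rng(7)
        geno = simulate_genotypes(cfg, rng)
        truth = simulate_effects(cfg, rng)
        for col in truth.columns:
            if col.startswith(("beta_", "delta_")):
                truth[col] = 0.0
        tiny = dataclasses.replace(cfg, residual_cov=np.eye(3) * 1e-16)
        pheno, t2 = simulate_phenotypes(geno, truth, tiny, rng)
        a0, a1, a2 = tiny.covariate_effects
        expect = (
            a0
            + a1 * pheno.table["time"].to_numpy()
            + a2 * pheno.table["covariate"].to_numpy()
        )
        assert np.abs(pheno.table["value"].to_numpy() - expect).max() < 1e-6

    def test_two_visits_with_intervals_in_range(self):
        data = simulate_dataset(small_config(), np.random.default_rng(8))
        counts = data.phenotypes.table.groupby(["individual_id", "trait_id"]).size()
        assert (counts == 2).all()
        assert data.intervals.min() >= 4.0 and data.intervals.max() <= 9.0

    def test_doubling_effects_quadruples_genetic_variance(self):
        cfg = small_config(n_individuals=100)
        rng = np.random.default_rng(9)
        data = simulate_dataset(cfg, rng)
        base = data.true_variance_components().C
        data.truth[[c for c in data.truth.columns if c.startswith(("beta_", "delta_"))]] *= 2.0
        doubled = data.true_variance_components().C
        assert np.allclose(doubled, 4.0 * base)

    def test_baseline_variance_decomposition(self):
        cfg = small_config(n_individuals=8000, n_variants=2000, n_causal=50)
        rng = np.random.default_rng(10)
        data = simulate_dataset(cfg, rng)
        vt = data.true_variance_components()
        base = data.phenotypes.table.query("time == 0")
        for k, trait in enumerate(cfg.traits):
            observed = base.loc[base.trait_id == trait, "value"].var()
            expected = vt.C[2 * k, 2 * k] + cfg.covariate_effects[2] ** 2 + vt.E[k, k]
            assert abs(observed - expected) < 0.12 * expected

    def test_bitwise_reproducibility(self):
        cfg = small_config()
        d1 = simulate_dataset(cfg, 123)
        d2 = simulate_dataset(cfg, 123)
        assert np.array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
        pd.testing.assert_frame_equal(d1.phenotypes.table, d2.phenotypes.table)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)
        d3 = simulate_dataset(cfg, 124)
        assert not np.array_equal(d1.genotypes.dosages, d3.genotypes.dosages)


class TestMacFilter:
    def test_all_zero_dosage_fails(self, rng):
        data = simulate_dataset(small_config(n_individuals=3000), rng)
        geno = data.genotypes
        geno.dosages[0] = 0
        mask = apply_mac_filter(geno, data.intervals)
        assert not mask[0]

    def test_common_variant_passes(self, rng):
        data = simulate_dataset(small_config(n_individuals=3000), rng)
        freq = data.genotypes.variants["freq"].to_numpy()
        mask = apply_mac_filter(data.genotypes, data.intervals)
        assert mask[freq > 0.3].all()

    def test_pass_fraction_near_table_arithmetic(self):
        # at n=3000 roughly two thirds of Beta(2,10)+0.01 variants are tested
        data = simulate_dataset(
            small_config(n_individuals=3000, n_variants=4000), np.random.default_rng(11)
        )
        mask = apply_mac_filter(data.genotypes, data.intervals)
        assert 0.55 < mask.mean() < 0.80

    def test_literal_frequency_rule(self, rng):
        data = simulate_dataset(small_config(n_individuals=500), rng)
        mask = apply_mac_filter(data.genotypes, data.intervals, rule="dosage_time")
        both = apply_mac_filter(data.genotypes, data.intervals, rule="both")
        cat = apply_mac_filter(data.genotypes, data.intervals, rule="category")
        assert (both <= mask).all() and (both <= cat).all()

    def test_unknown_rule(self, rng):
        data = simulate_dataset(small_config(n_individuals=100, n_variants=50), rng)
        with pytest.raises(ValueError, match="unknown MAC rule"):
            apply_mac_filter(data.genotypes, data.intervals, rule="nope")


class TestMissingness:
    def test_zero_fraction_identity(self, rng):
        data = simulate_dataset(small_config(), rng)
        out = inject_missingness(data.phenotypes, 0.0, "records", "trait1", 0)
        pd.testing.assert_frame_equal(out.table, data.phenotypes.table)

    def test_individual_mode_counts(self):
        data = simulate_dataset(small_config(n_individuals=1000), np.random.default_rng(12))
        out = inject_missingness(data.phenotypes, 0.5, "individuals", "trait1", 13)
        per_ind = out.table.groupby("individual_id")["trait_id"].nunique()
        assert (per_ind == 2).sum() == 500
        assert (per_ind == 3).sum() == 500

    def test_record_mode_conserves_other_traits(self):
        data = simulate_dataset(small_config(n_individuals=400), np.random.default_rng(13))
        before = data.phenotypes.table
        out = inject_missingness(data.phenotypes, 0.15, "records", "trait2", 14)
        for trait in ("trait1", "trait3"):
            assert (out.table.trait_id == trait).sum() == (before.trait_id == trait).sum()
        kept = (out.table.trait_id == "trait2").sum()
        assert kept == round(0.85 * (before.trait_id == "trait2").sum())

    def test_seeded_reproducibility(self, rng):
        data = simulate_dataset(small_config(), rng)
        a = inject_missingness(data.phenotypes, 0.3, "records", "trait1", 55)
        b = inject_missingness(data.phenotypes, 0.3, "records", "trait1", 55)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_fraction(self, rng):
        data = simulate_dataset(small_config(n_individuals=50, n_variants=50), rng)
        with pytest.raises(ValueError, match="fraction"):
            inject_missingness(data.phenotypes, 1.0, "records", "trait1", 0)
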