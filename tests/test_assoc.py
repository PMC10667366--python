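"""Association engine against dense mixed-model and GLS oracles."""

import numpy as np
import pandas as pd
import pytest

from mtlgwas.assoc import test_snp as bordered_single_snp
from mtlgwas.assoc import (
    build_null_system,
    pvalue,
    rate_of_change_gwas,
    scan_variants,
    single_trait_scan,
    write_summary_stats,
)
from mtlgwas.design import build_design, build_snp_design
from mtlgwas.genotypes import GenotypeDosage
from mtlgwas.phenotypes import PhenotypeLong
from mtlgwas.varcomp import VarianceComponents

from conftest import (
    dense_mixed_model,
    make_genotypes,
    make_phenotypes,
    random_spd,
    simulate_from_model,
)


class TestPvalue:
    def test_zero_effect_gives_one(self):
        assert pvalue(0.0, 1.0) == 1.0

    def test_normal_quantile(self):
        assert abs(pvalue(1.959964, 1.0) - 0.05) < 1e-6

    def test_sign_symmetry(self):
        assert pvalue(0.7, 0.3) == pvalue(-0.7, 0.3)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pvalue(1.0, 0.0)


def _vc_for(design, rng, scale_c=1.0, scale_e=1.0):
    k = design.n_traits
    return VarianceComponents(
        traits=design.traits,
        C=random_spd(2 * k, rng, scale_c),
        E=random_spd(k, rng, scale_e),
    )


class TestNullSystem:
    def test_hand_sized_matches_dense_mixed_model_equations(self, rng):
        pheno = make_phenotypes(3, 1, rng)
        ds = build_design(pheno, ["cov"])
        vc = _vc_for(ds, rng)
        ns = build_null_system(ds, vc)
        z_full, x_full, y, g_full, v_full = dense_mixed_model(ds, vc.C, vc.E)
        r_inv = np.linalg.inv(np.kron(vc.E, np.eye(ds.n_records)))
        lhs = np.block(
            [
                [x_full.T @ r_inv @ x_full, x_full.T @ r_inv @ z_full],
                [
                    z_full.T @ r_inv @ x_full,
                    z_full.T @ r_inv @ z_full + np.linalg.inv(g_full),
                ],
            ]
        )
        rhs = np.concatenate([x_full.T @ r_inv @ y, z_full.T @ r_inv @ y])
        sol = np.linalg.solve(lhs, rhs)
        p_tot = x_full.shape[1]
        assert np.abs(sol[:p_tot] - ns.b_hat).max() < 1e-8
        u_ns = np.zeros(len(sol) - p_tot)
        n_ind = ds.n_individuals
        for k in range(ds.n_traits):
            for i in range(n_ind):
                u_ns[k * 2 * n_ind + 2 * i : k * 2 * n_ind + 2 * i + 2] = ns.u_hat[
                    i, 2 * k : 2 * k + 2
                ]
        assert np.abs(sol[p_tot:] - u_ns).max() < 1e-8
        assert ns.residual_rel < 1e-8

    def test_zero_phenotype_gives_zero_solutions(self, rng):
        pheno = make_phenotypes(4, 2, rng)
        table = pheno.table.copy()
        table["value"] = 0.0
        ds = build_design(PhenotypeLong(table), ["cov"], scale_covariates=False)
        ns = build_null_system(ds, _vc_for(ds, rng))
        assert np.abs(ns.b_hat).max() < 1e-12
        assert np.abs(ns.u_hat).max() < 1e-12

    def test_fixed_core_dimension(self, rng):
        pheno = make_phenotypes(5, 3, rng)
        ds = build_design(pheno, ["cov"])
        ns = build_null_system(ds, _vc_for(ds, rng))
        # traits x per-trait fixed-effect count (intercept, time, covariate)
        assert ns.fixed_core_inv.shape == (9, 9)

    def test_collinear_covariates_named(self, rng):
        pheno = make_phenotypes(10, 1, rng)
        table = pheno.table.copy()
        table["cov2"] = table["cov"]
        ds = build_design(PhenotypeLong(table), ["cov", "cov2"])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            build_null_system(ds, _vc_for(ds, rng))


def _gls_oracle(design, vc, dosage_row):
    _, x_full, y, _, v_full = dense_mixed_model(design, vc.C, vc.E)
    w = build_snp_design(dosage_row, design).W_blockdiag()
    f_mat = np.hstack([w, x_full])
    v_inv = np.linalg.inv(v_full)
    cov = np.linalg.inv(f_mat.T @ v_inv @ f_mat)
    est = cov @ f_mat.T @ v_inv @ y
    k2 = w.shape[1]
    return est[:k2], np.sqrt(np.diag(cov)[:k2])


class TestBorderedScan:
    @pytest.mark.parametrize(
        "k_tot,n_ind,missing", [(1, 30, 0.0), (2, 50, 0.0), (3, 25, 0.25)]
    )
    def test_matches_dense_gls(self, rng, k_tot, n_ind, missing):
        pheno = make_phenotypes(n_ind, k_tot, rng, missing_rate=missing)
        ds = build_design(pheno, ["cov"])
        vc = _vc_for(ds, rng)
        ns = build_null_system(ds, vc)
        geno = make_genotypes(5, ds.individuals, rng)
        res = scan_variants(geno, ns)
        for j in range(5):
            beta, se = _gls_oracle(ds, vc, geno.dosages[j])
            assert np.abs(
                (res.beta[j].reshape(-1) - beta) / (np.abs(beta) + 1e-12)
            ).max() < 1e-8
            assert np.abs((res.se[j].reshape(-1) - se) / se).max() < 1e-8

    def test_zero_dosage_variant_filtered(self, rng):
        pheno = make_phenotypes(10, 2, rng)
        ds = build_design(pheno, ["cov"])
        ns = build_null_system(ds, _vc_for(ds, rng))
        geno = make_genotypes(2, ds.individuals, rng)
        geno.dosages[0] = 0.0
        res = scan_variants(geno, ns)
        assert res.variants.loc[0, "filter_status"] == "monomorphic"
        assert np.isnan(res.beta[0]).all()
        assert res.variants.loc[1, "filter_status"] == "tested"

    def test_invariance_to_individual_and_variant_order(self, rng):
        pheno = make_phenotypes(20, 2, rng, missing_rate=0.15)
        ds = build_design(pheno, ["cov"])
        vc = _vc_for(ds, rng)
        geno = make_genotypes(6, ds.individuals, rng)
        base = scan_variants(geno, build_null_system(ds, vc)).to_frame()

        perm_i = rng.permutation(len(pheno.table))
        pheno2 = PhenotypeLong(pheno.table.iloc[perm_i])
        ds2 = build_design(pheno2, ["cov"])
        perm_v = rng.permutation(geno.n_variants)
        geno2 = GenotypeDosage(
            geno.variants.iloc[perm_v].reset_index(drop=True),
            geno.individuals,
            geno.dosages[perm_v],
        )
        other = scan_variants(geno2, build_null_system(ds2, vc)).to_frame()
        pd.testing.assert_frame_equal(
            base.reset_index(drop=True), other.reset_index(drop=True)
        )

    def test_single_variant_wrapper(self, rng):
        pheno = make_phenotypes(12, 2, rng)
        ds = build_design(pheno, ["cov"])
        ns = build_null_system(ds, _vc_for(ds, rng))
        w = build_snp_design(rng.integers(0, 3, 12).astype(float), ds)
        frame = bordered_single_snp(ns, w)
        assert len(frame) == 4  # 2 traits x (CS, LT)
        assert (frame["p"] > 0).all() and (frame["p"] <= 1).all()

    def test_summary_stats_written_sorted(self, rng, tmp_path):
        pheno = make_phenotypes(10, 2, rng)
        ds = build_design(pheno, ["cov"])
        ns = build_null_system(ds, _vc_for(ds, rng))
        geno = make_genotypes(4, ds.individuals, rng)
        res = scan_variants(geno, ns)
        path = tmp_path / "sumstats.tsv"
        write_summary_stats(res, path)
        out = pd.read_csv(path, sep="\t")
        assert list(out.columns[:5]) == ["variant_id", "chrom", "pos", "ref", "alt"]
        assert (out["pos"].diff().fillna(0) >= 0).all()


class TestSingleTraitReduction:
    def test_joint_k1_equals_single_trait(self, rng):
        pheno = make_phenotypes(15, 1, rng)
        ds = build_design(pheno, ["cov"])
        vc = _vc_for(ds, rng)
        ns = build_null_system(ds, vc)
        geno = make_genotypes(4, ds.individuals, rng)
        joint = scan_variants(geno, ns)
        single = single_trait_scan(pheno, ds.traits[0], geno, vc, ["cov"])
        assert np.allclose(joint.beta, single.beta, equal_nan=True)
        assert np.allclose(joint.se, single.se, equal_nan=True)

    def test_decoupled_traits_match_single_scans(self, rng):
        c_mat = np.kron(np.eye(2), np.array([[3.0, 0.2], [0.2, 1.0]]))
        e_mat = np.diag([2.0, 1.5])
        pheno = simulate_from_model(150, c_mat, e_mat, rng)
        ds = build_design(pheno, ["cov"])
        vc = VarianceComponents(ds.traits, c_mat, e_mat)
        geno = make_genotypes(6, ds.individuals, rng)
        joint = scan_variants(geno, build_null_system(ds, vc))
        for k, trait in enumerate(ds.traits):
            single = single_trait_scan(pheno, trait, geno, vc, ["cov"])
            assert np.abs(joint.beta[:, k] - single.beta[:, 0]).max() < 1e-8
            assert np.abs(joint.se[:, k] - single.se[:, 0]).max() < 1e-8


class TestRateOfChange:
    def test_rate_definition(self, rng):
        rows = []
        for i, (y0, y1, t1) in enumerate([(10.0, 14.0, 4.0), (5.0, 5.0, 5.0)]):
            rows += [
                dict(individual_id=f"i{i}", trait_id="T", time=0.0, value=y0),
                dict(individual_id=f"i{i}", trait_id="T", time=t1, value=y1),
            ]
        # add spread so the baseline covariate is not constant
        for i in range(2, 30):
            t1 = 4 + (i % 5)
            rows += [
                dict(individual_id=f"i{i}", trait_id="T", time=0.0, value=float(i)),
                dict(individual_id=f"i{i}", trait_id="T", time=t1, value=float(i) + 0.1 * i),
            ]
        pheno = PhenotypeLong(pd.DataFrame(rows))
        geno = make_genotypes(3, [f"i{i}" for i in range(30)], rng)
        out = rate_of_change_gwas(pheno, geno)["T"]
        assert (out["n_used"] == 30).all()

    def test_constant_phenotype_no_signal(self, rng):
        rows = []
        for i in range(40):
            rows += [
                dict(individual_id=f"i{i}", trait_id="T", time=0.0, value=1.0 + 1e-6 * i),
                dict(individual_id=f"i{i}", trait_id="T", time=5.0, value=1.0 + 1e-6 * i),
            ]
        pheno = PhenotypeLong(pd.DataFrame(rows))
        geno = make_genotypes(5, [f"i{i}" for i in range(40)], rng)
        out = rate_of_change_gwas(pheno, geno)["T"]
        # all rates are exactly zero: no variant can reach significance
        assert np.allclose(out["beta"], 0.0)
        assert not (out["p"] < 0.05 / 5).any()

    def test_individuals_without_two_visits_dropped(self, rng):
        rows = []
        for i in range(30):
            rows.append(dict(individual_id=f"i{i}", trait_id="T", time=0.0, value=float(i)))
            if i < 25:
                rows.append(
                    dict(individual_id=f"i{i}", trait_id="T", time=4.0 + i % 3, value=i + rng.normal())
                )
        pheno = PhenotypeLong(pd.DataFrame(rows))
        geno = make_genotypes(2, [f"i{i}" for i in range(30)], rng)
        out = rate_of_change_gwas(pheno, geno)["T"]
        assert (out["n_used"] == 25).all()
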