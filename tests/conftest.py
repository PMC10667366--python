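"""Shared fixtures and builders for small synthetic instances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtlgwas.blockmat import BlockMatrix
from mtlgwas.genotypes import GenotypeDosage
from mtlgwas.phenotypes import PhenotypeLong


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_spd(order, rng, scale=1.0):
    a = rng.normal(size=(order, order))
    return scale * (a @ a.T + order * np.eye(order))


def structured_matrix(k_tot, n_ind, rng, decoupled_groups=None):
    """A Z'R^-1Z + G^-1 style block matrix with (N, 2, 2) stacked bands.

    ``decoupled_groups`` optionally partitions the traits into groups with
    no cross-group coupling (structural zeros).
    """
    groups = decoupled_groups or [list(range(k_tot))]
    blocks = {}
    t = rng.uniform(4, 9, n_ind)
    t_cross = np.zeros((n_ind, 2, 2))
    for i in range(n_ind):
        z_i = np.array([[1.0, 0.0], [1.0, t[i]]])
        t_cross[i] = z_i.T @ z_i
    for group in groups:
        kg = len(group)
        e_inv = np.linalg.inv(random_spd(kg, rng))
        c_inv = np.linalg.inv(random_spd(2 * kg, rng))
        for a, ka in enumerate(group):
            for b, kb in enumerate(group):
                blk = e_inv[a, b] * t_cross + np.broadcast_to(
                    c_inv[2 * a : 2 * a + 2, 2 * b : 2 * b + 2], (n_ind, 2, 2)
                )
                blocks[(ka, kb)] = blk.copy()
    return BlockMatrix(k_tot, n_ind, 2, blocks, symmetric=True)


def make_phenotypes(
    n_ind,
    k_tot,
    rng,
    missing_rate=0.0,
    value_scale=1.0,
    baseline_shift=0.0,
):
    """Two-visit phenotypes with one time-independent covariate."""
    traits = [f"T{k + 1}" for k in range(k_tot)]
    rows = []
    for i in range(n_ind):
        t2 = rng.uniform(4, 9)
        cov = rng.normal()
        for t in (0.0, t2):
            for k in range(k_tot):
                if missing_rate and rng.random() < missing_rate and not (
                    t == 0.0 and k == 0
                ):
                    continue
                rows.append(
                    {
                        "individual_id": f"i{i:04d}",
                        "trait_id": traits[k],
                        "time": t,
                        "value": baseline_shift + value_scale * rng.normal(),
                        "cov": cov,
                    }
                )
    return PhenotypeLong(pd.DataFrame(rows))


def make_genotypes(n_variants, individuals, rng, freq_range=(0.1, 0.5)):
    freq = rng.uniform(*freq_range, size=n_variants)
    dosages = rng.binomial(2, freq[:, None], size=(n_variants, len(individuals)))
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(n_variants)],
            "chrom": "1",
            "pos": np.arange(1, n_variants + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeDosage(variants, list(individuals), dosages.astype(float))


def simulate_from_model(n_ind, c_mat, e_mat, rng, beta_time=0.5, beta_cov=0.8):
    """Phenotypes drawn exactly from the random intercept/slope model."""
    k_tot = e_mat.shape[0]
    traits = [f"T{k + 1}" for k in range(k_tot)]
    u = rng.multivariate_normal(np.zeros(2 * k_tot), c_mat, size=n_ind)
    cov = rng.normal(size=n_ind)
    t2 = rng.uniform(4, 9, size=n_ind)
    rows = []
    for i in range(n_ind):
        for t in (0.0, t2[i]):
            eps = rng.multivariate_normal(np.zeros(k_tot), e_mat)
            for k in range(k_tot):
                val = (
                    1.0
                    + beta_time * t
                    + beta_cov * cov[i]
                    + u[i, 2 * k]
                    + u[i, 2 * k + 1] * t
                    + eps[k]
                )
                rows.append(
                    {
                        "individual_id": f"i{i:04d}",
                        "trait_id": traits[k],
                        "time": t,
                        "value": val,
                        "cov": cov[i],
                    }
                )
    return PhenotypeLong(pd.DataFrame(rows))


def dense_mixed_model(design, c_mat, e_mat):
    """Dense Z, X, y, V for oracle computations on small designs."""
    k_tot, n_ind, n = design.n_traits, design.n_individuals, design.n_records
    z_full = np.zeros((n * k_tot, 2 * n_ind * k_tot))
    for k in range(k_tot):
        z_full[k * n : (k + 1) * n, k * 2 * n_ind : (k + 1) * 2 * n_ind] = (
            design.Z_dense(k)
        )
    x_full = design.X_blockdiag()
    y = design.y_stacked()
    g_full = np.zeros((2 * n_ind * k_tot, 2 * n_ind * k_tot))
    for k in range(k_tot):
        for kp in range(k_tot):
            for i in range(n_ind):
                g_full[
                    k * 2 * n_ind + 2 * i : k * 2 * n_ind + 2 * i + 2,
                    kp * 2 * n_ind + 2 * i : kp * 2 * n_ind + 2 * i + 2,
                ] = c_mat[2 * k : 2 * k + 2, 2 * kp : 2 * kp + 2]
    r_full = np.kron(e_mat, np.eye(n))
    v_full = z_full @ g_full @ z_full.T + r_full
    return z_full, x_full, y, g_full, v_full
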