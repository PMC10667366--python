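"""Association engine: transformed null system and per-variant bordering.

The mixed-model equations are pre-multiplied by ``diag(I, B)`` with
``B = (Z'R^-1 Z + G^-1)^-1`` (computed once by recursive partitioning) so
the large random-effects block becomes an identity.  The null solutions
``b_hat, u_hat`` are stored; each variant then only borders the system with
its 2K SNP equations (one cross-sectional and one longitudinal effect per
trait), and the 2K x 2K Schur matrix is the only per-variant inverse.

All per-variant quantities are linear in the dosage vector g (or g^2)
against per-individual tensors that depend only on the null system, so a
scan reduces to a few dosage-matrix products followed by batched small
solves.  Wald p-values are two-sided standard-normal tail areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blockmat import recursive_partition_inverse
from .design import DesignSet, SnpDesign, build_design, build_G_inverse, build_snp_design
from .genotypes import GenotypeDosage
from .phenotypes import PhenotypeLong
from .varcomp import VarianceComponents

__all__ = [
    "NullSystem",
    "SnpResults",
    "build_null_system",
    "test_snp",
    "scan_variants",
    "single_trait_scan",
    "rate_of_change_gwas",
    "pvalue",
    "write_summary_stats",
]

logger = logging.getLogger(__name__)

P_FLOOR = 5e-324  # smallest positive subnormal double


def pvalue(beta, se):
    """Two-sided Wald p-value: twice the upper standard-normal tail of |beta/se|."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    p = np.maximum(p, P_FLOOR)
    if p.ndim == 0:
        return float(p)
    return p


@dataclass
class NullSystem:
    """Cached transformed null model for one design + variance components.

    ``fixed_core_inv`` is the inverse of ``M11 - M12 M21``, whose order is
    the number of traits times the per-trait fixed-effect count.  The stored
    per-individual tensors make each variant's bordered solve a dosage-
    weighted contraction.
    """

    design: DesignSet
    vc: VarianceComponents
    e_inv: np.ndarray  # (K, K)
    B: object  # BlockMatrix inverse of Z'R^-1Z + G^-1
    M11: np.ndarray  # (P, P)
    M12: np.ndarray  # (N, P, 2K)
    M21: np.ndarray  # (N, 2K, P)
    fixed_core_inv: np.ndarray  # (P, P)
    r1: np.ndarray  # (P,)
    r2: np.ndarray  # (N, 2K)
    b_hat: np.ndarray  # (P,)
    u_hat: np.ndarray  # (N, 2K)
    residual_rel: float
    # per-individual scan tensors
    ZRX: np.ndarray  # (N, 2K, P)
    H11_pre: np.ndarray  # (N, 2K, 2K): blocks e^kk' * per-individual Z'Z cross
    schur_pre: np.ndarray  # (N, 2K, 2K): H11_pre - H11_pre Q
    rho_pre: np.ndarray  # (N, P, 2K): M12 - M12 Q
    a1_pre: np.ndarray  # (N, 2K, P): ZRX - H11_pre M21
    rhs_pre: np.ndarray  # (N, 2K)

    @property
    def null_solutions(self) -> np.ndarray:
        """Stacked [b_hat; u_hat] solving the transformed system."""
        return np.concatenate([self.b_hat, self.u_hat.reshape(-1)])


def _per_individual_cross(design: DesignSet):
    """Per-individual cross products of masked [1, dt] blocks and X, y."""
    k_tot, n_ind = design.n_traits, design.n_individuals
    ind = design.row_individual
    t_mat = design.T
    p_tot = sum(design.p)
    x_stack = np.zeros((design.n_records, p_tot))
    col = 0
    for k, xk in enumerate(design.X):
        x_stack[:, col : col + xk.shape[1]] = xk
        col += xk.shape[1]

    t_masked = [t_mat * design.obs[k][:, None] for k in range(k_tot)]
    t_cross = np.zeros((k_tot, k_tot, n_ind, 2, 2))
    t_y = np.zeros((k_tot, k_tot, n_ind, 2))
    xt_all = np.zeros((k_tot, n_ind, p_tot, 2))
    for k in range(k_tot):
        for kp in range(k, k_tot):
            outer = t_masked[k][:, :, None] * t_masked[kp][:, None, :]
            acc = np.zeros((n_ind, 2, 2))
            np.add.at(acc, ind, outer)
            t_cross[k, kp] = acc
            if kp != k:
                t_cross[kp, k] = np.swapaxes(acc, -1, -2)
        for kp in range(k_tot):
            acc = np.zeros((n_ind, 2))
            np.add.at(acc, ind, t_masked[k] * design.Y[kp][:, None])
            t_y[k, kp] = acc
        acc = np.zeros((n_ind, p_tot, 2))
        np.add.at(acc, ind, x_stack[:, :, None] * t_masked[k][:, None, :])
        xt_all[k] = acc
    return x_stack, t_cross, t_y, xt_all


def build_null_system(design: DesignSet, vc: VarianceComponents) -> NullSystem:
    """Precompute the transformed system of the null (no-SNP) model."""
    k_tot, n_ind = design.n_traits, design.n_individuals
    p_tot = sum(design.p)
    if list(vc.traits) != list(design.traits):
        vc = vc.restrict(design.traits)
    e_mat = vc.E
    w_e = np.linalg.eigvalsh(e_mat)
    if w_e[0] < 1e-4 * w_e[-1]:
        # a nearly singular residual covariance (weakly identified when the
        # polygenic variance dominates) would make E^-1-scaled blocks cancel
        # catastrophically in the bordered solves; floor its spectrum
        from .varcomp import _floor_spd

        e_mat, adj = _floor_spd(e_mat, floor_rel=1e-4)
        logger.warning(
            "residual covariance nearly singular (eigenvalues %.3e..%.3e); "
            "floored spectrum for numerical stability (max adjustment %.3e)",
            w_e[0],
            w_e[-1],
            adj,
        )
    e_inv = np.linalg.inv(e_mat)
    e_inv = (e_inv + e_inv.T) / 2.0

    x_stack, t_cross, t_y, xt_all = _per_individual_cross(design)
    trait_of_col = np.concatenate(
        [np.full(pk, k) for k, pk in enumerate(design.p)]
    ).astype(int)

    # random-effects block M = Z'R^-1Z + G^-1 and its recursive inverse
    g_inv = build_G_inverse(vc.C, n_ind)
    m_blocks = {}
    for k in range(k_tot):
        for kp in range(k_tot):
            blk = e_inv[k, kp] * t_cross[k, kp]
            gblk = g_inv.blocks.get((k, kp))
            if gblk is not None:
                blk = blk + gblk
            if np.any(blk != 0.0) or k == kp:
                m_blocks[(k, kp)] = blk
    from .blockmat import BlockMatrix

    m_mat = BlockMatrix(k_tot, n_ind, 2, m_blocks, symmetric=True)
    b_inv = recursive_partition_inverse(m_mat)
    b_stack = np.zeros((n_ind, 2 * k_tot, 2 * k_tot))
    m_stack = np.zeros((n_ind, 2 * k_tot, 2 * k_tot))
    for (k, kp), blk in b_inv.blocks.items():
        b_stack[:, 2 * k : 2 * k + 2, 2 * kp : 2 * kp + 2] = blk
    for (k, kp), blk in m_blocks.items():
        m_stack[:, 2 * k : 2 * k + 2, 2 * kp : 2 * kp + 2] = blk

    # fixed-effect blocks: M11 block (k, k') = e^kk' X_k' X_k'
    col_off = np.concatenate([[0], np.cumsum(design.p)])
    m11 = np.zeros((p_tot, p_tot))
    for k in range(k_tot):
        for kp in range(k_tot):
            m11[col_off[k] : col_off[k + 1], col_off[kp] : col_off[kp + 1]] = (
                e_inv[k, kp] * (design.X[k].T @ design.X[kp])
            )
    # M12 (N, P, 2K): column block k' is sum_k e^kk' XT (rows live in trait blocks)
    m12 = np.einsum(
        "pk,knpa->npka",
        e_inv[trait_of_col, :],
        xt_all,
    ).reshape(n_ind, p_tot, 2 * k_tot)
    # Z'R^-1X (N, 2K, P)
    zrx = np.zeros((n_ind, 2 * k_tot, p_tot))
    for k in range(k_tot):
        for kp in range(k_tot):
            cols = trait_of_col == kp
            zrx[:, 2 * k : 2 * k + 2, cols] = e_inv[k, kp] * np.swapaxes(
                xt_all[k][:, cols, :], -1, -2
            )
    # B times an R^-1-scaled quantity cancels internally; a per-individual
    # solve with M keeps the error proportional to the small result rather
    # than to ||B|| times the large operand
    m21 = np.linalg.solve(m_stack, zrx)
    fixed_core = m11 - np.einsum("npq,nqr->pr", m12, m21)
    cond = np.linalg.cond(fixed_core)
    if not np.isfinite(cond) or cond > 1e14:
        names = [
            f"{design.traits[k]}:{name}"
            for k in range(k_tot)
            for name in design.x_names[k]
        ]
        _, r_diag = np.linalg.qr(fixed_core)
        dep = [
            names[j]
            for j in range(p_tot)
            if abs(r_diag[j, j]) < 1e-8 * abs(r_diag[0, 0])
        ]
        raise np.linalg.LinAlgError(
            f"fixed-effect equations are collinear (condition {cond:.3e}); "
            f"dependent columns: {dep or 'unresolved'}"
        )
    fixed_core_inv = np.linalg.inv(fixed_core)

    # right-hand sides and null solutions
    x_y = np.zeros((k_tot, p_tot))
    for kp in range(k_tot):
        x_y[kp] = x_stack.T @ design.Y[kp]
    r1 = np.einsum("pk,kp->p", e_inv[trait_of_col, :], x_y)
    zry = np.einsum("kc,kcna->nka", e_inv, t_y).reshape(n_ind, -1)
    # note: einsum above sums over the second trait index c of t_y[k, c]
    r2 = np.linalg.solve(m_stack, zry[:, :, None])[:, :, 0]
    b_hat = fixed_core_inv @ (r1 - np.einsum("npq,nq->p", m12, r2))
    u_hat = r2 - np.einsum("nqp,p->nq", m21, b_hat)

    # residual of the transformed system (relative)
    lhs_top = m11 @ b_hat + np.einsum("npq,nq->p", m12, u_hat)
    lhs_bot = np.einsum("nqp,p->nq", m21, b_hat) + u_hat
    num = np.linalg.norm(lhs_top - r1) ** 2 + np.linalg.norm(lhs_bot - r2) ** 2
    den = np.linalg.norm(r1) ** 2 + np.linalg.norm(r2) ** 2
    residual_rel = float(np.sqrt(num / den)) if den > 0 else 0.0

    # scan tensors.  The Woodbury forms H - H B H etc. cancel catastrophically
    # when R^-1 is large (ill-conditioned residual covariance), so the exact
    # product-only identities implied by B^-1 = H + G^-1 are used instead:
    #   H - H B H   = G^-1 - G^-1 B G^-1      (W'V^-1 W tensor)
    #   (I - H B)'  = B G^-1 on the left      (a1, rho, rhs tensors)
    h11_pre = np.zeros((n_ind, 2 * k_tot, 2 * k_tot))
    g_inv_blk = np.zeros((n_ind, 2 * k_tot, 2 * k_tot))
    for k in range(k_tot):
        for kp in range(k_tot):
            h11_pre[:, 2 * k : 2 * k + 2, 2 * kp : 2 * kp + 2] = (
                e_inv[k, kp] * t_cross[k, kp]
            )
            gblk = g_inv.blocks.get((k, kp))
            if gblk is not None:
                g_inv_blk[:, 2 * k : 2 * k + 2, 2 * kp : 2 * kp + 2] = gblk
    schur_pre = g_inv_blk - g_inv_blk @ (b_stack @ g_inv_blk)
    m12_b = np.swapaxes(
        np.linalg.solve(m_stack, np.swapaxes(m12, -1, -2)), -1, -2
    )  # M12 B via solve (B symmetric)
    rho_pre = m12_b @ g_inv_blk
    a1_pre = g_inv_blk @ m21
    rhs_pre = (g_inv_blk @ u_hat[:, :, None])[:, :, 0]
    return NullSystem(
        design=design,
        vc=vc,
        e_inv=e_inv,
        B=b_inv,
        M11=m11,
        M12=m12,
        M21=m21,
        fixed_core_inv=fixed_core_inv,
        r1=r1,
        r2=r2,
        b_hat=b_hat,
        u_hat=u_hat,
        residual_rel=residual_rel,
        ZRX=zrx,
        H11_pre=h11_pre,
        schur_pre=schur_pre,
        rho_pre=rho_pre,
        a1_pre=a1_pre,
        rhs_pre=rhs_pre,
    )


@dataclass
class SnpResults:
    """Per-variant, per-trait CS and LT effects, standard errors, p-values."""

    variants: pd.DataFrame  # variant metadata + filter_status
    traits: list
    beta: np.ndarray  # (V, K, 2): [..., 0]=CS, [..., 1]=LT
    se: np.ndarray
    p: np.ndarray
    n_used: np.ndarray  # (K,) individuals contributing per trait

    def to_frame(self) -> pd.DataFrame:
        rows = []
        eff_names = ("CS", "LT")
        for k, trait in enumerate(self.traits):
            for e in range(2):
                sub = self.variants.copy()
                sub["trait"] = trait
                sub["effect"] = eff_names[e]
                sub["beta"] = self.beta[:, k, e]
                sub["se"] = self.se[:, k, e]
                sub["p"] = self.p[:, k, e]
                sub["n_used"] = self.n_used[k]
                rows.append(sub)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(
            ["chrom", "pos", "variant_id", "trait", "effect"], kind="mergesort"
        ).reset_index(drop=True)


def scan_variants(
    geno: GenotypeDosage,
    ns: NullSystem,
    tested_mask=None,
    chunk_size: int = 1024,
) -> SnpResults:
    """Test every variant against a prebuilt null system.

    ``tested_mask`` marks variants passing upstream filters (e.g. the
    minor-allele-count rule); others are reported with ``filter_status``
    ``failed_mac``.  Variants monomorphic across retained individuals are
    filtered rather than raising.
    """
    design = ns.design
    k_tot = design.n_traits
    n_ind = design.n_individuals
    p_tot = sum(design.p)
    dosage = geno.dosage_for(design.individuals)  # (V, N)
    n_var = dosage.shape[0]
    if tested_mask is None:
        tested_mask = np.ones(n_var, dtype=bool)
    tested_mask = np.asarray(tested_mask, dtype=bool).copy()
    status = np.where(tested_mask, "tested", "failed_mac").astype(object)
    bad_dosage = ~np.all(np.isfinite(dosage), axis=1)
    status[bad_dosage & tested_mask] = "missing_dosage"
    tested_mask &= ~bad_dosage
    mono = np.nanstd(dosage, axis=1) == 0.0
    status[mono & tested_mask] = "monomorphic"
    tested_mask &= ~mono

    two_k = 2 * k_tot
    beta = np.full((n_var, k_tot, 2), np.nan)
    se = np.full((n_var, k_tot, 2), np.nan)
    pvals = np.full((n_var, k_tot, 2), np.nan)

    # flatten per-individual tensors once for dosage-matrix products
    g1_cols = np.concatenate(
        [
            ns.rho_pre.reshape(n_ind, -1),
            ns.a1_pre.reshape(n_ind, -1),
            ns.rhs_pre,
        ],
        axis=1,
    )
    g2_cols = ns.schur_pre.reshape(n_ind, -1)
    split1 = p_tot * two_k
    split2 = split1 + two_k * p_tot

    idx_all = np.nonzero(tested_mask)[0]
    for start in range(0, len(idx_all), chunk_size):
        idx = idx_all[start : start + chunk_size]
        g = np.ascontiguousarray(dosage[idx])
        y1 = g @ g1_cols
        y2 = (g**2) @ g2_cols
        nv = len(idx)
        rho = y1[:, :split1].reshape(nv, p_tot, two_k)
        a1 = y1[:, split1:split2].reshape(nv, two_k, p_tot)
        rhs = y1[:, split2:]
        schur_g2 = y2.reshape(nv, two_k, two_k)
        bpart = np.einsum("pq,vqk->vpk", ns.fixed_core_inv, rho)
        schur = schur_g2 - a1 @ bpart
        schur = (schur + np.swapaxes(schur, -1, -2)) / 2.0
        ok = np.ones(nv, dtype=bool)
        # guard nearly singular Schur matrices (e.g. dosage constant within
        # the informative subset)
        diag = np.einsum("vii->vi", schur)
        ok &= np.all(diag > 0, axis=1)
        cov = np.full_like(schur, np.nan)
        if ok.any():
            try:
                cov[ok] = np.linalg.inv(schur[ok])
            except np.linalg.LinAlgError:
                for j in np.nonzero(ok)[0]:
                    try:
                        cov[j] = np.linalg.inv(schur[j])
                    except np.linalg.LinAlgError:
                        ok[j] = False
        var_diag = np.einsum("vii->vi", cov)
        ok &= np.all(var_diag > 0, axis=1)
        b = np.einsum("vpq,vq->vp", cov, rhs)
        s = np.sqrt(np.where(var_diag > 0, var_diag, np.nan))
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(b / s))
        p = np.maximum(p, P_FLOOR)
        beta[idx] = b.reshape(nv, k_tot, 2)
        se[idx] = s.reshape(nv, k_tot, 2)
        pvals[idx] = p.reshape(nv, k_tot, 2)
        bad = idx[~ok]
        beta[bad] = np.nan
        se[bad] = np.nan
        pvals[bad] = np.nan
        status[bad] = "singular"
        tested_mask[bad] = False

    variants = geno.variants.copy()
    variants["filter_status"] = status
    n_used = np.array(
        [
            int(np.unique(design.row_individual[design.obs[k]]).size)
            for k in range(k_tot)
        ]
    )
    return SnpResults(
        variants=variants,
        traits=list(design.traits),
        beta=beta,
        se=se,
        p=pvals,
        n_used=n_used,
    )


def test_snp(ns: NullSystem, w: SnpDesign) -> pd.DataFrame:
    """Bordered-system estimates for a single variant (one row per trait/effect)."""
    geno = GenotypeDosage(
        pd.DataFrame(
            [{"variant_id": "snp", "chrom": "0", "pos": 0, "ref": "A", "alt": "B"}]
        ),
        list(ns.design.individuals),
        w.dosage[None, :],
    )
    return scan_variants(geno, ns).to_frame()


def single_trait_scan(
    pheno: PhenotypeLong,
    trait: str,
    geno: GenotypeDosage,
    vc: VarianceComponents,
    fixed_effects=None,
    tested_mask=None,
) -> SnpResults:
    """Single-trait longitudinal GWAS: the K=1 reduction of the engine.

    Individuals without any record of the trait drop out, which is how the
    single-trait comparator loses sample size under missing data.
    """
    sub = pheno.restrict_traits([trait])
    earliest = sub.table.groupby("individual_id")["time"].min()
    no_baseline = set(earliest[earliest != 0.0].index)
    if no_baseline:
        logger.info(
            "single-trait scan %s: dropped %d individuals without a baseline "
            "record of the trait",
            trait,
            len(no_baseline),
        )
        sub = PhenotypeLong(sub.table[~sub.table["individual_id"].isin(no_baseline)])
    design = build_design(sub, fixed_effects)
    ns = build_null_system(design, vc.restrict([trait]))
    return scan_variants(geno, ns, tested_mask=tested_mask)


def rate_of_change_gwas(
    pheno: PhenotypeLong,
    geno: GenotypeDosage,
    traits=None,
    covariates=None,
) -> dict:
    """Comparator GWAS on per-individual rates of change.

    For each trait, individuals with exactly two time points contribute
    ``(y2 - y1) / dt``; the model regresses the rate on dosage with the
    scaled baseline measurement (and optional time-independent covariates)
    but no time term.  Returns ``{trait: DataFrame}`` with normal-theory
    Wald statistics.
    """
    table = pheno.table
    traits = traits or pheno.traits
    out = {}
    for trait in traits:
        sub = table[table["trait_id"] == trait]
        counts = sub.groupby("individual_id")["time"].nunique()
        keep = counts[counts == 2].index
        dropped = int((counts != 2).sum())
        if dropped:
            logger.info(
                "rate-of-change %s: dropped %d individuals without exactly "
                "2 time points",
                trait,
                dropped,
            )
        sub = sub[sub["individual_id"].isin(keep)].sort_values(
            ["individual_id", "time"]
        )
        first = sub.groupby("individual_id").first()
        last = sub.groupby("individual_id").last()
        dt = (last["time"] - first["time"]).to_numpy()
        nonzero = dt > 0
        if (~nonzero).any():
            logger.info(
                "rate-of-change %s: excluded %d individuals with zero "
                "time interval",
                trait,
                int((~nonzero).sum()),
            )
        ids = first.index.to_numpy()[nonzero]
        rate = ((last["value"] - first["value"]).to_numpy() / np.where(dt == 0, 1, dt))[
            nonzero
        ]
        baseline = first["value"].to_numpy()[nonzero]
        cols = [np.ones(len(ids)), (baseline - baseline.mean()) / baseline.std()]
        names = ["intercept", "baseline"]
        for c in covariates or []:
            vals = first[c].to_numpy(dtype=float)[nonzero]
            sd = vals.std()
            cols.append((vals - vals.mean()) / sd if sd > 0 else vals)
            names.append(c)
        x_mat = np.column_stack(cols)
        dosage = geno.dosage_for(ids)  # (V, m)
        m = len(ids)
        # residualise rate and dosages on covariates
        qx, _ = np.linalg.qr(x_mat)
        resid_y = rate - qx @ (qx.T @ rate)
        resid_g = dosage - (dosage @ qx) @ qx.T
        gg = np.einsum("vi,vi->v", resid_g, resid_g)
        gy = resid_g @ resid_y
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(gg > 0, gy / np.where(gg == 0, 1, gg), np.nan)
            rss = resid_y @ resid_y - beta * gy
            dof = m - x_mat.shape[1] - 1
            sigma2 = rss / dof
            se = np.sqrt(sigma2 / np.where(gg == 0, np.nan, gg))
        with np.errstate(invalid="ignore"):
            p = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), P_FLOOR)
        res = geno.variants.copy()
        res["trait"] = trait
        res["beta"] = beta
        res["se"] = se
        res["p"] = p
        res["n_used"] = m
        out[trait] = res
    return out


def write_summary_stats(results: SnpResults, path) -> None:
    """Tab-separated long-format summary statistics, sorted by position."""
    frame = results.to_frame()
    cols = [
        "variant_id",
        "chrom",
        "pos",
        "ref",
        "alt",
        "trait",
        "effect",
        "beta",
        "se",
        "p",
        "n_used",
        "filter_status",
    ]
    frame[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
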