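"""Variance-component estimation by pairwise bivariate AI-REML.

The null model (no SNPs) for traits k, k' is a bivariate random
intercept/slope model: per individual, u_i ~ N(0, C_pair) with C_pair the
4x4 covariance of (CS_k, LT_k, CS_k', LT_k') effects and residuals
correlated across traits at the same visit through the 2x2 block E_pair.
Average-information REML maximises the restricted likelihood over all
C_pair and E_pair entries jointly, with step halving to keep the restricted
likelihood non-decreasing and variance floors at the positivity boundary.

Full K-trait matrices are assembled from the K(K-1)/2 pairwise fits: each
trait's own 2x2 genetic block (and residual variance) is averaged over its
K-1 fits, while cross-trait covariances are unique to their pair; the
assembly is repaired to positive definiteness by eigenvalue flooring.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design
from .phenotypes import PhenotypeLong

__all__ = [
    "VarianceComponents",
    "PairwiseFit",
    "NonConvergenceError",
    "fit_pairwise_aireml",
    "assemble_covariances",
    "estimate_variance_components",
    "enumerate_pairs",
    "heritability",
    "write_variance_components",
    "read_variance_components",
]

logger = logging.getLogger(__name__)

PD_FLOOR_REL = 1e-8  # eigenvalue floor relative to the largest eigenvalue


class NonConvergenceError(RuntimeError):
    """AI-REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    """Genetic (2K x 2K) and residual (K x K) covariance matrices.

    ``C`` is trait-major with entries (2k, 2k+1) the CS and LT components of
    trait k; ``E`` is the residual covariance between traits at a shared
    visit.  ``provenance`` records how many pairwise estimates were averaged
    into each diagonal block.
    """

    traits: list[str]
    C: np.ndarray
    E: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.traits)
        self.C = np.asarray(self.C, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.C.shape != (2 * k, 2 * k) or self.E.shape != (k, k):
            raise ValueError("C must be 2Kx2K and E KxK for K traits")
        if not (np.allclose(self.C, self.C.T) and np.allclose(self.E, self.E.T)):
            raise ValueError("C and E must be symmetric")

    def restrict(self, traits) -> "VarianceComponents":
        """Sub-matrices for a subset of traits (e.g. a single-trait scan)."""
        idx = [self.traits.index(t) for t in traits]
        gi = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
        return VarianceComponents(
            traits=list(traits),
            C=self.C[np.ix_(gi, gi)],
            E=self.E[np.ix_(idx, idx)],
            provenance=self.provenance,
        )

    def labels(self) -> list[str]:
        return [f"{t}:{c}" for t in self.traits for c in ("CS", "LT")]


@dataclass
class PairwiseFit:
    traits: tuple
    genetic: np.ndarray  # 4x4 (CS1, LT1, CS2, LT2)
    residual: np.ndarray  # 2x2
    loglik: float
    trace: list
    converged: bool
    boundary: bool  # some variance pinned at the positivity floor


def enumerate_pairs(traits) -> list[tuple]:
    """The K(K-1)/2 trait pairs needing a bivariate variance-component fit."""
    return list(itertools.combinations(list(traits), 2))


# ---------------------------------------------------------------------------
# restricted likelihood machinery


class _RemlProblem:
    """Grouped per-individual arrays for a K-trait random intercept/slope model.

    Individuals are grouped by their observation pattern (which (trait,
    record) slots are present) so that every group is a rectangular stack on
    which V_i, its inverse and all derivative contractions vectorise.
    Unobserved slots are excluded entirely: they carry no information.
    """

    def __init__(self, pheno: PhenotypeLong, traits, fixed_effects=None):
        ds = build_design(pheno.restrict_traits(traits), fixed_effects)
        self.traits = ds.traits
        k_tot = ds.n_traits
        self.n_traits = k_tot
        self.p_total = sum(ds.p)
        col_off = np.concatenate([[0], np.cumsum(ds.p)])

        groups: dict[tuple, list] = {}
        for i in range(ds.n_individuals):
            rows = np.nonzero(ds.row_individual == i)[0]
            slots = [
                (k, r) for r in rows for k in range(k_tot) if ds.obs[k, r]
            ]
            if not slots:
                continue
            # pattern key: per-slot trait and within-individual record index
            rec_pos = {r: j for j, r in enumerate(rows)}
            key = tuple((k, rec_pos[r]) for k, r in slots)
            groups.setdefault(key, []).append((i, slots))
        self.groups = []
        for key, members in groups.items():
            m = len(key)
            ng = len(members)
            z = np.zeros((ng, m, 2 * k_tot))
            x = np.zeros((ng, m, self.p_total))
            y = np.zeros((ng, m))
            for gi, (i, slots) in enumerate(members):
                for s, (k, r) in enumerate(slots):
                    z[gi, s, 2 * k : 2 * k + 2] = ds.T[r]
                    x[gi, s, col_off[k] : col_off[k + 1]] = ds.X[k][r]
                    y[gi, s] = ds.Y[k, r]
            # residual coupling: slots sharing the record index
            res_pairs = np.zeros((m, m), dtype=int) - 1
            for a, (ka, pa) in enumerate(key):
                for b, (kb, pb) in enumerate(key):
                    if pa == pb:
                        res_pairs[a, b] = ka * k_tot + kb
            self.groups.append({"Z": z, "X": x, "y": y, "res": res_pairs, "n": ng})
        self.n_individuals = sum(g["n"] for g in self.groups)
        self.n_obs = sum(g["n"] * g["Z"].shape[1] for g in self.groups)

        # parameter layout: vech(C) then vech(E)
        self.c_params = [
            (a, b) for a in range(2 * k_tot) for b in range(a, 2 * k_tot)
        ]
        self.e_params = [(s, t) for s in range(k_tot) for t in range(s, k_tot)]
        self.n_par = len(self.c_params) + len(self.e_params)
        self._build_dv()

    def _build_dv(self):
        for g in self.groups:
            z, res = g["Z"], g["res"]
            ng, m, _ = z.shape
            dv = np.zeros((self.n_par, ng, m, m))
            for j, (a, b) in enumerate(self.c_params):
                outer = z[:, :, a, None] * z[:, None, :, b]
                dv[j] = outer + np.swapaxes(outer, -1, -2) if a != b else outer
            off = len(self.c_params)
            k_tot = self.n_traits
            for j, (s, t) in enumerate(self.e_params):
                mask = (res == s * k_tot + t) | (res == t * k_tot + s)
                dv[off + j] = mask.astype(float)[None, :, :]
            g["dV"] = dv

    # -- parameter packing -------------------------------------------------

    def pack(self, c_mat, e_mat) -> np.ndarray:
        return np.concatenate(
            [
                [c_mat[a, b] for a, b in self.c_params],
                [e_mat[s, t] for s, t in self.e_params],
            ]
        )

    def unpack(self, theta):
        k2 = 2 * self.n_traits
        c_mat = np.zeros((k2, k2))
        for j, (a, b) in enumerate(self.c_params):
            c_mat[a, b] = c_mat[b, a] = theta[j]
        e_mat = np.zeros((self.n_traits, self.n_traits))
        off = len(self.c_params)
        for j, (s, t) in enumerate(self.e_params):
            e_mat[s, t] = e_mat[t, s] = theta[off + j]
        return c_mat, e_mat

    # -- restricted likelihood, score, average information ------------------

    def loglik(self, theta):
        return self._evaluate(theta, derivatives=False)[0]

    def _evaluate(self, theta, derivatives=True):
        p = self.p_total
        xtvix = np.zeros((p, p))
        xtviy = np.zeros(p)
        logdet_v = 0.0
        cache = []
        for g in self.groups:
            v = np.tensordot(theta, g["dV"], axes=(0, 0))  # (ng, m, m)
            if not np.all(np.isfinite(v)):
                return -np.inf, None, None
            sign, ld = np.linalg.slogdet(v)
            if not np.all(sign > 0):
                return -np.inf, None, None
            logdet_v += ld.sum()
            vinv = np.linalg.inv(v)
            u = vinv @ g["X"]  # (ng, m, p)
            ng, m, _ = u.shape
            xtvix += g["X"].reshape(ng * m, p).T @ u.reshape(ng * m, p)
            xtviy += u.reshape(ng * m, p).T @ g["y"].reshape(ng * m)
            cache.append((vinv, u))
        sign_f, logdet_f = np.linalg.slogdet(xtvix)
        if sign_f <= 0:
            return -np.inf, None, None
        beta = np.linalg.solve(xtvix, xtviy)

        ypy = 0.0
        f_inv = np.linalg.inv(xtvix)
        if derivatives:
            n_par = self.n_par
            score = np.zeros(n_par)
            t2 = np.zeros((n_par, p, p))
            xvf = np.zeros((n_par, p))
            fvif = np.zeros((n_par, n_par))
        for g, (vinv, u) in zip(self.groups, cache):
            resid = g["y"] - g["X"] @ beta  # (ng, m)
            w = (vinv @ resid[:, :, None])[:, :, 0]  # (Py)_i blocks
            ypy += float(resid.reshape(-1) @ w.reshape(-1))
            if not derivatives:
                continue
            dv = g["dV"]  # (n_par, ng, m, m)
            ng, m = w.shape
            # tr(V^-1 dV_j) and X'V^-1 dV_j V^-1 X as flattened BLAS products
            vinv_t = np.swapaxes(vinv, -1, -2).reshape(-1)
            score -= 0.5 * (dv.reshape(n_par, -1) @ vinv_t)
            dv_u = dv @ u  # (n_par, ng, m, p) batched
            t2 += np.swapaxes(
                u.reshape(ng * m, p).T[None] @ dv_u.reshape(n_par, ng * m, p), 0, 0
            )
            f = (dv @ w[None, :, :, None])[..., 0]  # dV_j (Py): (n_par, ng, m)
            score += 0.5 * (f.reshape(n_par, -1) @ w.reshape(-1))
            fv = (vinv[None] @ f[..., None])[..., 0]  # V^-1 f_j
            fvif += f.reshape(n_par, -1) @ fv.reshape(n_par, -1).T
            xvf += f.reshape(n_par, -1) @ u.reshape(ng * m, p)
        ll = -0.5 * (logdet_v + logdet_f + ypy)
        if not np.isfinite(ll):
            return -np.inf, None, None
        if not derivatives:
            return ll, None, None
        score += 0.5 * np.einsum("ab,pba->p", f_inv, t2)
        ai = 0.5 * (fvif - xvf @ f_inv @ xvf.T)
        return ll, score, ai

    # -- initial values ----------------------------------------------------

    def initial_theta(self) -> np.ndarray:
        """Method-of-moments starting values.

        Within an individual, the covariance between a trait's baseline and
        another visit's measurement contains no residual term, so it
        estimates the CS (co)variance; baseline covariances then yield the
        residual block, and follow-up variance inflation divided by the
        mean squared interval gives the LT variances.  Moments come from
        the largest observation-pattern group (residualised on the fixed
        effects crudely via the mean); anything unavailable falls back to a
        simple variance split.  The start is floored to PD.
        """
        k_tot = self.n_traits
        big = max(self.groups, key=lambda g: g["n"])
        z, y = big["Z"], big["y"]
        m = z.shape[1]
        slot_trait = np.array([int(np.argmax(z[0, s, 0::2] != 0)) for s in range(m)])
        is_base = np.array(
            [bool(np.allclose(z[:, s, 2 * slot_trait[s] + 1], 0.0)) for s in range(m)]
        )
        s_cov = np.cov(y.T) if big["n"] > 2 else np.eye(m)
        s_cov = np.atleast_2d(s_cov)
        t_follow = np.concatenate(
            [
                z[:, s, 2 * slot_trait[s] + 1]
                for s in range(m)
                if not is_base[s]
            ]
        ) if (~is_base).any() else np.array([5.5])
        tbar2 = float(np.mean(t_follow**2))

        def slot_of(k, base):
            hits = [s for s in range(m) if slot_trait[s] == k and is_base[s] == base]
            return hits[0] if hits else None

        c_mat = np.zeros((2 * k_tot, 2 * k_tot))
        e_mat = np.zeros((k_tot, k_tot))
        var0 = np.ones(k_tot)
        for k in range(k_tot):
            sb, sf = slot_of(k, True), slot_of(k, False)
            v0 = s_cov[sb, sb] if sb is not None else (
                s_cov[sf, sf] if sf is not None else 1.0
            )
            var0[k] = max(float(v0), 1e-6)
            cs = (
                float(s_cov[sb, sf])
                if sb is not None and sf is not None
                else var0[k] / 3.0
            )
            cs = float(np.clip(cs, 1e-3 * var0[k], (1 - 1e-3) * var0[k]))
            res = max(var0[k] - cs, 1e-3 * var0[k])
            fv = float(s_cov[sf, sf]) if sf is not None else var0[k]
            lt = max((fv - cs - res) / tbar2, 1e-3 * var0[k] / tbar2)
            c_mat[2 * k, 2 * k] = cs
            c_mat[2 * k + 1, 2 * k + 1] = lt
            e_mat[k, k] = res
        for k in range(k_tot):
            for kp in range(k + 1, k_tot):
                sb_k, sf_k = slot_of(k, True), slot_of(k, False)
                sb_p, sf_p = slot_of(kp, True), slot_of(kp, False)
                vals = [
                    s_cov[a, b]
                    for a, b in ((sb_k, sf_p), (sb_p, sf_k))
                    if a is not None and b is not None
                ]
                if vals:
                    cap = 0.9 * np.sqrt(c_mat[2 * k, 2 * k] * c_mat[2 * kp, 2 * kp])
                    c_mat[2 * k, 2 * kp] = c_mat[2 * kp, 2 * k] = float(
                        np.clip(np.mean(vals), -cap, cap)
                    )
                if sb_k is not None and sb_p is not None:
                    res_kk = float(s_cov[sb_k, sb_p]) - c_mat[2 * k, 2 * kp]
                    cap = 0.9 * np.sqrt(e_mat[k, k] * e_mat[kp, kp])
                    e_mat[k, kp] = e_mat[kp, k] = float(np.clip(res_kk, -cap, cap))
        c_mat = _floor_spd(c_mat, floor_rel=1e-6)[0]
        e_mat = _floor_spd(e_mat, floor_rel=1e-6)[0]
        return self.pack(c_mat, e_mat)


def _floor_spd(mat: np.ndarray, floor_rel=PD_FLOOR_REL):
    """Eigenvalue-floored SPD repair; returns (repaired, max adjustment)."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    floor = floor_rel * max(w[-1], floor_rel)
    w_fixed = np.maximum(w, floor)
    repaired = (v * w_fixed) @ v.T
    return (repaired + repaired.T) / 2.0, float(np.abs(repaired - mat).max())


def _tril_indices(order):
    return [(a, b) for a in range(order) for b in range(a + 1)]


def _chol_jacobian(problem, l_fac, m_fac):
    """d vech(C)/d tril(L) and d vech(E)/d tril(M) for C=LL', E=MM'."""
    n_par = problem.n_par
    jac = np.zeros((n_par, n_par))
    lc = _tril_indices(2 * problem.n_traits)
    le = _tril_indices(problem.n_traits)
    for j, (a, b) in enumerate(lc):
        for i, (p, q) in enumerate(problem.c_params):
            val = 0.0
            if p == a:
                val += l_fac[q, b]
            if q == a:
                val += l_fac[p, b]
            jac[i, j] = val
    off_r, off_c = len(problem.c_params), len(lc)
    for j, (a, b) in enumerate(le):
        for i, (p, q) in enumerate(problem.e_params):
            val = 0.0
            if p == a:
                val += m_fac[q, b]
            if q == a:
                val += m_fac[p, b]
            jac[off_r + i, off_c + j] = val
    return jac


def _fit_reml(problem: _RemlProblem, max_iter=100, tol=1e-6):
    """Maximise the restricted likelihood by damped average-information steps.

    The optimiser works on Cholesky factors of C and E, which keeps both
    matrices positive (semi-)definite at every iterate and lets boundary
    optima (vanishing variance components) be approached smoothly; the
    score and average-information matrix are mapped into factor space
    through the Jacobian of C = LL', E = MM'.
    """
    c0, e0 = problem.unpack(problem.initial_theta())
    l_fac = np.linalg.cholesky(c0)
    m_fac = np.linalg.cholesky(e0)
    lc = _tril_indices(2 * problem.n_traits)
    le = _tril_indices(problem.n_traits)

    def factors_to_theta(lf, mf):
        return problem.pack(lf @ lf.T, mf @ mf.T)

    def unpack_fac(vec):
        lf = np.zeros_like(l_fac)
        mf = np.zeros_like(m_fac)
        for j, (a, b) in enumerate(lc):
            lf[a, b] = vec[j]
        for j, (a, b) in enumerate(le):
            mf[a, b] = vec[len(lc) + j]
        return lf, mf

    def pack_fac(lf, mf):
        return np.concatenate(
            [[lf[a, b] for a, b in lc], [mf[a, b] for a, b in le]]
        )

    fac = pack_fac(l_fac, m_fac)
    fac_scale = float(np.abs(fac).max())
    theta = factors_to_theta(l_fac, m_fac)
    ll, score, ai = problem._evaluate(theta)
    if not np.isfinite(ll):
        raise NonConvergenceError(
            "restricted likelihood undefined at the starting values "
            "(singular fixed-effect design or covariance)",
            [],
        )
    trace = [{"iteration": 0, "loglik": ll, "damping": 0.0}]
    scale = max(float(np.abs(theta).max()), 1e-8)
    floor = PD_FLOOR_REL * scale
    boundary = False
    converged = False
    n_c = len(problem.c_params)
    var_idx = [j for j, (a, b) in enumerate(problem.c_params) if a == b] + [
        n_c + j for j, (s, t) in enumerate(problem.e_params) if s == t
    ]
    lam_start = 0.0
    plateau = 0
    for it in range(1, max_iter + 1):
        jac = _chol_jacobian(problem, *unpack_fac(fac))
        score_f = jac.T @ score
        ai_f = jac.T @ ai @ jac
        damp_scale = np.maximum(
            np.diag(ai_f), 1e-10 * max(np.abs(ai_f).max(), 1.0)
        )
        lam = lam_start  # carry damping over from the previous iteration
        accepted = False
        for _ in range(18):
            try:
                direction = np.linalg.solve(
                    ai_f + lam * np.diag(damp_scale), score_f
                )
            except np.linalg.LinAlgError:
                direction = None
            if direction is not None and np.all(np.isfinite(direction)):
                for step in (1.0, 0.5, 0.25):
                    fac_trial = fac + step * direction
                    # guard against runaway excursions along flat ridges
                    if np.abs(fac_trial).max() > 1e6 * (fac_scale + 1.0):
                        continue
                    theta_trial = factors_to_theta(*unpack_fac(fac_trial))
                    ll_trial = problem.loglik(theta_trial)
                    if np.isfinite(ll_trial) and ll_trial >= ll - 1e-9:
                        accepted = True
                        break
            if accepted:
                break
            lam = 1e-4 if lam == 0.0 else lam * 10.0
        if not accepted:
            # no ascent step exists even under heavy damping: at the optimum
            converged = True
            break
        lam_start = lam / 10.0 if lam > 1e-4 else 0.0
        delta = np.abs(theta_trial - theta) / (np.abs(theta) + 1.0)
        d_ll = ll_trial - ll
        # canonicalise factor signs (columns are defined up to sign; keeping
        # diagonals nonnegative avoids stalls at the sign-flip degeneracy)
        lf_new, mf_new = unpack_fac(fac_trial)
        for mat in (lf_new, mf_new):
            flip = np.diag(mat) < 0
            mat[:, flip] *= -1.0
        fac, theta = pack_fac(lf_new, mf_new), theta_trial
        ll, score, ai = problem._evaluate(theta)
        trace.append({"iteration": it, "loglik": ll, "damping": lam})
        if abs(d_ll) < tol and delta.max() < tol:
            converged = True
            break
        # secondary criterion: the restricted likelihood has plateaued while
        # parameters drift along a flat ridge or sit on the PD boundary
        if abs(d_ll) < tol:
            plateau += 2 if lam <= 1e-2 else 1
        else:
            plateau = 0
        if plateau >= 4:
            converged = True
            break
    if not converged:
        err = NonConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", trace
        )
        vars_ = theta[var_idx]
        err.last_state = (
            *problem.unpack(theta),
            ll,
            bool(vars_.min() < 1e-5 * max(float(vars_.max()), 1e-300)),
        )
        raise err
    c_mat, e_mat = problem.unpack(theta)
    # boundary diagnostic: a variance collapsed to (numerically) zero
    vars_ = theta[var_idx]
    boundary = bool(vars_.min() < 1e-5 * max(float(vars_.max()), 1e-300))
    return c_mat, e_mat, ll, trace, boundary


def fit_pairwise_aireml(
    pheno: PhenotypeLong,
    trait_pair,
    fixed_effects=None,
    min_individuals=50,
    max_iter=100,
    tol=1e-6,
    on_nonconvergence="raise",
) -> PairwiseFit:
    """Bivariate AI-REML for one trait pair on the null (no-SNP) model.

    ``on_nonconvergence="use_last"`` returns the final iterate (flagged
    ``converged=False``, with a logged warning) instead of raising; useful
    in replicated scenario runs where a rare slow fit should not abort the
    study.
    """
    t1, t2 = trait_pair
    if t1 == t2:
        raise ValueError("pairwise variance-component fits need two distinct traits")
    table = pheno.table
    for t in (t1, t2):
        counts = (
            table[table["trait_id"] == t].groupby("individual_id")["time"].nunique()
        )
        n_long = int((counts >= 2).sum())
        if n_long < min_individuals:
            raise ValueError(
                f"trait {t!r} has only {n_long} individuals with >=2 time points "
                f"(minimum {min_individuals})"
            )
    problem = _RemlProblem(pheno, [t1, t2], fixed_effects)
    order = [problem.traits.index(t) for t in (t1, t2)]
    converged = True
    trace = []
    try:
        c_mat, e_mat, ll, trace, boundary = _fit_reml(problem, max_iter, tol)
    except NonConvergenceError as err:
        if on_nonconvergence != "use_last" or not hasattr(err, "last_state"):
            raise
        c_mat, e_mat, ll, boundary = err.last_state
        trace = err.trace
        converged = False
        logger.warning(
            "AI-REML for (%s, %s) stopped at max_iter=%d without meeting the "
            "convergence criterion; using the final iterate",
            t1,
            t2,
            max_iter,
        )
    gi = np.concatenate([[2 * i, 2 * i + 1] for i in order])
    return PairwiseFit(
        traits=(t1, t2),
        genetic=c_mat[np.ix_(gi, gi)],
        residual=e_mat[np.ix_(order, order)],
        loglik=ll,
        trace=trace,
        converged=converged,
        boundary=boundary,
    )


def assemble_covariances(pairwise_fits, traits) -> VarianceComponents:
    """Combine all K(K-1)/2 pairwise fits into full C (2Kx2K) and E (KxK).

    Per-trait blocks are means over that trait's pairwise fits; cross-trait
    blocks are unique.  The assembly is floored to positive definiteness.
    """
    traits = list(traits)
    k_tot = len(traits)
    fits = {}
    for fit in pairwise_fits:
        fits[frozenset(fit.traits)] = fit
    missing = [
        (a, b) for a, b in enumerate_pairs(traits) if frozenset((a, b)) not in fits
    ]
    if missing:
        raise ValueError(f"missing pairwise fits for trait pairs: {missing}")

    c_mat = np.zeros((2 * k_tot, 2 * k_tot))
    e_mat = np.zeros((k_tot, k_tot))
    diag_counts = np.zeros(k_tot, dtype=int)
    for (a, b) in enumerate_pairs(traits):
        fit = fits[frozenset((a, b))]
        ia, ib = traits.index(a), traits.index(b)
        first = fit.traits[0] == a
        g = fit.genetic if first else fit.genetic[np.ix_([2, 3, 0, 1], [2, 3, 0, 1])]
        r = fit.residual if first else fit.residual[::-1, ::-1]
        c_mat[2 * ia : 2 * ia + 2, 2 * ia : 2 * ia + 2] += g[:2, :2]
        c_mat[2 * ib : 2 * ib + 2, 2 * ib : 2 * ib + 2] += g[2:, 2:]
        c_mat[2 * ia : 2 * ia + 2, 2 * ib : 2 * ib + 2] = g[:2, 2:]
        c_mat[2 * ib : 2 * ib + 2, 2 * ia : 2 * ia + 2] = g[2:, :2]
        e_mat[ia, ia] += r[0, 0]
        e_mat[ib, ib] += r[1, 1]
        e_mat[ia, ib] = e_mat[ib, ia] = r[0, 1]
        diag_counts[ia] += 1
        diag_counts[ib] += 1
    if k_tot >= 2:
        for i in range(k_tot):
            c_mat[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] /= diag_counts[i]
            e_mat[i, i] /= diag_counts[i]
    # Positive-definiteness repair.  Averaged variances with unique pairwise
    # covariances can leave E indefinite (the CS/residual split is weakly
    # identified when polygenic variance dominates).  Flooring E's spectrum
    # alone would understate residual variance in the floored direction and
    # badly overstate precision downstream, so the amount removed from E is
    # shifted into the CS block of C: the fitted same-visit covariance
    # (C_CS + E), which is what the data identify well, is preserved exactly.
    e_floored, adj_e = _floor_spd(e_mat, floor_rel=1e-4)
    shift = e_mat - e_floored  # <= 0 in the floored directions
    for i in range(k_tot):
        for j in range(k_tot):
            c_mat[2 * i, 2 * j] += shift[i, j]
    e_mat = e_floored
    c_mat, adj_c = _floor_spd(c_mat)
    if max(adj_c, adj_e) > 0:
        logger.info(
            "positive-definiteness repair adjusted C by %.3e and E by %.3e",
            adj_c,
            adj_e,
        )
    return VarianceComponents(
        traits=traits,
        C=c_mat,
        E=e_mat,
        provenance={
            "pairwise_fits": len(fits),
            "averaged_per_trait": {t: int(c) for t, c in zip(traits, diag_counts)},
            "pd_adjustment": {"C": adj_c, "E": adj_e},
        },
    )


def estimate_variance_components(
    pheno: PhenotypeLong,
    fixed_effects=None,
    min_individuals=50,
    max_iter=500,
    tol=1e-6,
    on_nonconvergence="raise",
) -> VarianceComponents:
    """Run all pairwise fits and assemble the full matrices.

    With a single trait, a univariate random intercept/slope REML fit is
    used directly.
    """
    traits = pheno.traits
    if len(traits) == 1:
        problem = _RemlProblem(pheno, traits, fixed_effects)
        c_mat, e_mat, ll, trace, boundary = _fit_reml(problem, max_iter, tol)
        c_mat, _ = _floor_spd(c_mat)
        e_mat, _ = _floor_spd(e_mat)
        return VarianceComponents(traits=traits, C=c_mat, E=e_mat)
    fits = [
        fit_pairwise_aireml(
            pheno,
            pair,
            fixed_effects,
            min_individuals,
            max_iter,
            tol,
            on_nonconvergence=on_nonconvergence,
        )
        for pair in enumerate_pairs(traits)
    ]
    return assemble_covariances(fits, traits)


def heritability(vc: VarianceComponents) -> pd.DataFrame:
    """Per-trait polygenic heritability of the CS and LT components.

    ``h2_CS = var_CS / (var_CS + var_LT + var_residual)`` and analogously
    for LT, all from the null-model variance components (no relationship
    matrix is involved).
    """
    rows = []
    for k, trait in enumerate(vc.traits):
        var_cs = vc.C[2 * k, 2 * k]
        var_lt = vc.C[2 * k + 1, 2 * k + 1]
        var_res = vc.E[k, k]
        total = var_cs + var_lt + var_res
        if total <= 0:
            raise ValueError(f"total variance for trait {trait!r} is not positive")
        rows.append(
            {"trait": trait, "h2_CS": var_cs / total, "h2_LT": var_lt / total}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file round trip


def write_variance_components(vc: VarianceComponents, path) -> None:
    """Labelled TSV with the C and E matrices at 17 significant digits."""
    labels = vc.labels()
    with open(path, "w") as fh:
        fh.write("#C\n")
        fh.write("\t".join([""] + labels) + "\n")
        for lab, row in zip(labels, vc.C):
            fh.write("\t".join([lab] + [f"{x:.17g}" for x in row]) + "\n")
        fh.write("#E\n")
        fh.write("\t".join([""] + vc.traits) + "\n")
        for lab, row in zip(vc.traits, vc.E):
            fh.write("\t".join([lab] + [f"{x:.17g}" for x in row]) + "\n")


def read_variance_components(path) -> VarianceComponents:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    ic = lines.index("#C")
    ie = lines.index("#E")
    traits = lines[ie + 1].split("\t")[1:]
    k = len(traits)
    c_rows = [ln.split("\t")[1:] for ln in lines[ic + 2 : ic + 2 + 2 * k]]
    e_rows = [ln.split("\t")[1:] for ln in lines[ie + 2 : ie + 2 + k]]
    c_mat = np.array(c_rows, dtype=float)
    e_mat = np.array(e_rows, dtype=float)
    return VarianceComponents(traits=traits, C=c_mat, E=e_mat)
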