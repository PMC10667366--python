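"""Design and covariance structure construction for the multi-trait model.

The stacked observation vector is trait-major: ``y = (y_1', ..., y_K')'``
with each ``y_k`` laid out on a common record grid -- the union, over
individuals, of every time at which *any* trait was measured.  A trait
missing at a grid point occupies an all-zero row (zero in ``y``, ``X``,
``Z`` and the SNP design), which keeps the K trait blocks row-aligned so
that the residual precision ``E^-1 (x) I_n`` and the genetic precision
``I_N (x) C^kk'`` apply without bookkeeping.

Random effects are one intercept/slope pair per individual per trait; the
per-individual ``Z`` block is ``[1, dt]`` with ``dt`` the time from the
individual's baseline, so the baseline row's interval is always 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blockmat import BlockMatrix, KroneckerFactors, kron_inverse, _coupling_components
from .phenotypes import PhenotypeLong

__all__ = [
    "DesignSet",
    "SnpDesign",
    "build_design",
    "build_R_inverse",
    "build_G_inverse",
    "build_snp_design",
]

FIXED_BASE_COLUMNS = ("intercept", "time")


@dataclass
class DesignSet:
    """Aligned multi-trait design: y, X, Z and the record grid.

    ``n_records`` is n, the common per-trait row count; row ``r`` of every
    trait block refers to the same (individual, time) slot.  ``T`` holds the
    per-row ``[1, dt]`` random-effect covariates shared by all traits; trait
    k's effective Z rows are ``T * obs[k][:, None]``.
    """

    traits: list[str]
    individuals: np.ndarray  # (N,) individual ids, order of random-effect blocks
    row_individual: np.ndarray  # (n,) index into individuals
    row_time: np.ndarray  # (n,) years from baseline
    T: np.ndarray  # (n, 2) columns [1, dt], before per-trait masking
    obs: np.ndarray  # (K, n) observation mask
    Y: np.ndarray  # (K, n) measurements, zero where unobserved
    X: list  # per-trait (n, p_k) fixed-effect matrices, zero rows where unobserved
    x_names: list  # per-trait column labels
    scaling: dict = field(default_factory=dict)  # (trait, column) -> (mean, sd)

    # -- derived sizes -----------------------------------------------------

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_records(self) -> int:
        return len(self.row_time)

    @property
    def q(self) -> np.ndarray:
        """Records per individual on the union grid (sums to n)."""
        return np.bincount(self.row_individual, minlength=self.n_individuals)

    @property
    def p(self) -> list[int]:
        return [x.shape[1] for x in self.X]

    def record_index(self, individual_id, trait_id, time) -> int:
        """Row of (individual, trait, time); raises if the slot is unobserved."""
        iid = str(individual_id)
        k = self.traits.index(str(trait_id))
        rows = np.nonzero(
            (self.individuals[self.row_individual] == iid)
            & np.isclose(self.row_time, float(time))
        )[0]
        if len(rows) != 1 or not self.obs[k, rows[0]]:
            raise KeyError(f"no observed record for {(individual_id, trait_id, time)}")
        return int(rows[0])

    def missing_mask(self) -> np.ndarray:
        """(K, n) mask of inserted all-zero rows."""
        return ~self.obs

    def Z_dense(self, k: int) -> np.ndarray:
        """Dense n x 2N random-effect design of trait k (testing/small data)."""
        n, big_n = self.n_records, self.n_individuals
        z = np.zeros((n, 2 * big_n))
        rows = np.arange(n)
        tk = self.T * self.obs[k][:, None]
        z[rows, 2 * self.row_individual] = tk[:, 0]
        z[rows, 2 * self.row_individual + 1] = tk[:, 1]
        return z

    def y_stacked(self) -> np.ndarray:
        """Trait-major stacked phenotype vector of length nK."""
        return self.Y.reshape(-1)

    def X_blockdiag(self) -> np.ndarray:
        """Dense block-diagonal fixed-effect matrix (testing/small data)."""
        n, ps = self.n_records, self.p
        out = np.zeros((n * self.n_traits, sum(ps)))
        col = 0
        for k, xk in enumerate(self.X):
            out[k * n : (k + 1) * n, col : col + ps[k]] = xk
            col += ps[k]
        return out

    def follow_up_interval(self) -> np.ndarray:
        """Per-individual time of the latest record (years from baseline)."""
        out = np.zeros(self.n_individuals)
        np.maximum.at(out, self.row_individual, self.row_time)
        return out


def _is_indicator(values: np.ndarray) -> bool:
    u = np.unique(values[np.isfinite(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def build_design(pheno: PhenotypeLong, fixed_effects=None, scale_covariates=True) -> DesignSet:
    """Construct the aligned multi-trait design from a phenotype table.

    Parameters
    ----------
    pheno
        Validated long-format phenotypes.
    fixed_effects
        Covariate columns to include per trait beyond the always-present
        intercept and time columns: a list applied to every trait, or a
        mapping ``trait -> list``.  ``None`` uses every covariate column for
        every trait.
    scale_covariates
        Centre/scale continuous covariates to mean 0, variance 1 over each
        trait's observed rows; 0/1 indicators are left as-is.
    """
    table = pheno.table
    traits = pheno.traits
    if fixed_effects is None:
        fixed_effects = {k: pheno.covariate_columns for k in traits}
    elif not isinstance(fixed_effects, dict):
        fixed_effects = {k: list(fixed_effects) for k in traits}
    for k, cols in fixed_effects.items():
        for c in cols:
            if c not in table.columns:
                raise KeyError(f"covariate {c!r} for trait {k!r} not in phenotype table")

    # union record grid over (individual, time)
    grid = (
        table[["individual_id", "time"]]
        .drop_duplicates()
        .sort_values(["individual_id", "time"], kind="mergesort")
        .reset_index(drop=True)
    )
    earliest = grid.groupby("individual_id")["time"].min()
    off = earliest[earliest != 0.0]
    if len(off):
        raise ValueError(
            f"individual {off.index[0]!r} has no baseline (time 0) record"
        )
    individuals = pd.unique(grid["individual_id"])
    ind_index = pd.Series(np.arange(len(individuals)), index=individuals)
    row_individual = ind_index[grid["individual_id"]].to_numpy()
    row_time = grid["time"].to_numpy(dtype=float)
    n = len(grid)
    big_t = np.column_stack([np.ones(n), row_time])

    row_of = {
        (iid, t): r
        for r, (iid, t) in enumerate(zip(grid["individual_id"], grid["time"]))
    }

    n_traits = len(traits)
    obs = np.zeros((n_traits, n), dtype=bool)
    big_y = np.zeros((n_traits, n))
    xs, names, scaling = [], [], {}
    for k, trait in enumerate(traits):
        sub = table[table["trait_id"] == trait]
        rows = np.array([row_of[(iid, t)] for iid, t in zip(sub["individual_id"], sub["time"])])
        obs[k, rows] = True
        big_y[k, rows] = sub["value"].to_numpy(dtype=float)
        cols = list(fixed_effects[trait])
        xk = np.zeros((n, 2 + len(cols)))
        xk[rows, 0] = 1.0
        xk[rows, 1] = row_time[rows]
        for j, c in enumerate(cols):
            vals = sub[c].to_numpy(dtype=float)
            if np.isnan(vals).any():
                bad = sub.loc[np.isnan(vals), "individual_id"].iloc[0]
                raise ValueError(
                    f"covariate {c!r} missing for an observed record of "
                    f"individual {bad!r} (trait {trait!r})"
                )
            if scale_covariates and not _is_indicator(vals):
                mu, sd = float(vals.mean()), float(vals.std())
                if sd == 0.0:
                    raise ValueError(f"covariate {c!r} is constant for trait {trait!r}")
                vals = (vals - mu) / sd
                scaling[(trait, c)] = (mu, sd)
            xk[rows, 2 + j] = vals
        xs.append(xk)
        names.append(list(FIXED_BASE_COLUMNS) + cols)

    return DesignSet(
        traits=traits,
        individuals=np.asarray(individuals, dtype=object),
        row_individual=row_individual,
        row_time=row_time,
        T=big_t,
        obs=obs,
        Y=big_y,
        X=xs,
        x_names=names,
        scaling=scaling,
    )


def _check_spd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w[0] <= 0:
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue {w[0]:.6e})"
        )


def build_R_inverse(E: np.ndarray, n: int) -> BlockMatrix:
    """Residual precision ``E^-1 (x) I_n`` as a scalar-band block matrix."""
    _check_spd(E, "residual covariance E")
    return kron_inverse(KroneckerFactors(np.asarray(E, dtype=float), n))


def build_G_inverse(C: np.ndarray, n_individuals: int) -> BlockMatrix:
    """Genetic precision with (k, k') super-blocks ``I_N (x) C^kk'``.

    ``C`` is the 2K x 2K covariance of per-trait (CS, LT) random effects in
    trait-major order.  Traits in decoupled groups of ``C`` (exact zero
    cross-blocks) produce structurally absent super-blocks.
    """
    c_mat = np.asarray(C, dtype=float)
    _check_spd(c_mat, "genetic covariance C")
    k = c_mat.shape[0] // 2
    if c_mat.shape != (2 * k, 2 * k):
        raise ValueError("C must have even order 2K")
    coupled = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(k):
            coupled[a, b] = np.any(c_mat[2 * a : 2 * a + 2, 2 * b : 2 * b + 2] != 0.0)
    c_inv = np.zeros_like(c_mat)
    for comp in _coupling_components(coupled):
        idx = np.concatenate([[2 * t, 2 * t + 1] for t in comp])
        sub = np.ix_(idx, idx)
        inv = np.linalg.inv(c_mat[sub])
        c_inv[sub] = (inv + inv.T) / 2.0
    blocks = {}
    for a in range(k):
        for b in range(k):
            sub = c_inv[2 * a : 2 * a + 2, 2 * b : 2 * b + 2]
            if np.any(sub != 0.0) or a == b:
                blocks[(a, b)] = np.broadcast_to(sub, (n_individuals, 2, 2)).copy()
    return BlockMatrix(k, n_individuals, 2, blocks, symmetric=True)


@dataclass
class SnpDesign:
    """Per-variant design ``W = I (x) W_k``.

    For trait k, column 1 of ``W_k`` is the individual's dosage repeated on
    each of their rows and column 2 is column 1 times the time interval;
    rows missing for the trait are zeroed exactly as in the phenotype
    design.
    """

    design: DesignSet
    dosage: np.ndarray  # (N,) per-individual dosage

    def W_k(self, k: int) -> np.ndarray:
        g_rows = self.dosage[self.design.row_individual]
        return self.design.T * (g_rows * self.design.obs[k])[:, None]

    def W_blockdiag(self) -> np.ndarray:
        n, k_tot = self.design.n_records, self.design.n_traits
        out = np.zeros((n * k_tot, 2 * k_tot))
        for k in range(k_tot):
            out[k * n : (k + 1) * n, 2 * k : 2 * k + 2] = self.W_k(k)
        return out


def build_snp_design(dosages: np.ndarray, design: DesignSet) -> SnpDesign:
    """Align one variant's per-individual dosages with a design."""
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape != (design.n_individuals,):
        raise ValueError(
            f"need one dosage per retained individual "
            f"({design.n_individuals}), got shape {dosages.shape}"
        )
    if np.nanmin(dosages) < 0 or np.nanmax(dosages) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    return SnpDesign(design=design, dosage=dosages)
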