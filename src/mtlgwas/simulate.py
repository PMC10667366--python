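"""Synthetic multi-trait longitudinal GWAS data.

The generator draws independent biallelic variants with allele frequencies
Beta(2, 10) + 0.01 and Hardy-Weinberg genotypes; three correlated traits
receive cross-sectional (CS) and longitudinal (LT) variant effects from a
multivariate normal whose mean is 10 for CS effects and 10/L for LT
effects (L >= 1 attenuates trajectory effects relative to level effects).
A small random subset of variants is causal; all remaining variants carry
infinitesimal background effects drawn from the same distribution with
mean and covariance shrunk 1000-fold, forming the polygenic background the
null model's random intercepts/slopes absorb.  Phenotypes are observed at
baseline and one follow-up 4-9 years later, with residuals independent
across visits, one standard-normal time-independent covariate, and
optional record- or individual-level missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeDosage
from .phenotypes import PhenotypeLong
from .varcomp import VarianceComponents

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "apply_mac_filter",
    "inject_missingness",
]

logger = logging.getLogger(__name__)

VAR_CS = np.array([[10.0, 8.0, -7.0], [8.0, 12.0, -1.0], [-7.0, -1.0, 18.0]])
COV_CS_LT = np.array(
    [[0.5, 0.4, -0.35], [0.4, 0.6, -0.05], [-0.35, -0.05, 0.9]]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulation.

    ``lt_attenuation`` is L: expected LT effects are ``mean_cs_effect / L``
    and their covariance is ``var_cs / L``; the CS-LT cross-covariance
    block is held fixed.  ``residual_cov`` defaults to the CS effect
    covariance matrix.
    """

    n_individuals: int = 3000
    n_variants: int = 10_000
    n_causal: int = 100
    n_traits: int = 3
    lt_attenuation: float = 1.0
    mean_cs_effect: float = 10.0
    var_cs: np.ndarray = field(default_factory=lambda: VAR_CS.copy())
    cov_cs_lt: np.ndarray = field(default_factory=lambda: COV_CS_LT.copy())
    residual_cov: np.ndarray | None = None
    maf_beta_params: tuple = (2.0, 10.0)
    maf_offset: float = 0.01
    time_range_years: tuple = (4.0, 9.0)
    covariate_effects: tuple = (0.0, 1.0, 1.0)  # alpha0, alpha1, alpha2

    def __post_init__(self):
        k = self.n_traits
        var_cs = np.asarray(self.var_cs, dtype=float)
        cov = np.asarray(self.cov_cs_lt, dtype=float)
        if var_cs.shape != (k, k) or cov.shape != (k, k):
            raise ValueError(f"effect covariance blocks must be {k}x{k}")
        if self.lt_attenuation < 1.0:
            raise ValueError("lt_attenuation (L) must be >= 1")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        object.__setattr__(self, "var_cs", var_cs)
        object.__setattr__(self, "cov_cs_lt", cov)
        res = self.residual_cov
        res = var_cs.copy() if res is None else np.asarray(res, dtype=float)
        object.__setattr__(self, "residual_cov", res)

    @property
    def traits(self) -> list:
        return [f"trait{k + 1}" for k in range(self.n_traits)]

    def effect_mean(self) -> np.ndarray:
        """Mean vector of (beta_1..K, delta_1..K)."""
        mu = self.mean_cs_effect
        return np.concatenate(
            [np.full(self.n_traits, mu), np.full(self.n_traits, mu / self.lt_attenuation)]
        )

    def effect_cov(self) -> np.ndarray:
        """Assembled 2K x 2K effect covariance; raises if not PD."""
        sigma = np.block(
            [
                [self.var_cs, self.cov_cs_lt],
                [self.cov_cs_lt.T, self.var_cs / self.lt_attenuation],
            ]
        )
        w = np.linalg.eigvalsh(sigma)
        if w[0] <= 0:
            raise ValueError(
                f"assembled effect covariance is not positive definite "
                f"(smallest eigenvalue {w[0]:.6e})"
            )
        return sigma


@dataclass
class SimulatedDataset:
    genotypes: GenotypeDosage
    phenotypes: PhenotypeLong
    truth: pd.DataFrame  # per-variant frequency, causal flag, effect columns
    config: SimulationConfig
    intervals: np.ndarray  # (N,) follow-up time per individual

    def effect_matrix(self) -> np.ndarray:
        """(V, 2K) effects ordered (beta_1..K, delta_1..K)."""
        k = self.config.n_traits
        cols = [f"beta_{t}" for t in self.config.traits] + [
            f"delta_{t}" for t in self.config.traits
        ]
        return self.truth[cols].to_numpy()

    def true_variance_components(self) -> VarianceComponents:
        """Realized polygenic covariance implied by the drawn effects.

        Individual i's genetic value for trait k is sum_r beta_rk g_ir with
        an analogous slope term; with independent Hardy-Weinberg variants
        the between-individual covariance is sum_r a_r a_r' var(g_r), using
        the realized dosage variance of each variant.
        """
        k = self.config.n_traits
        a = self.effect_matrix()  # (V, 2K) ordered CS-block then LT-block
        g_var = self.genotypes.dosages.astype(float).var(axis=1)
        cov_type = np.einsum("v,va,vb->ab", g_var, a, a)
        # reorder from (CS block, LT block) to trait-major (CS_k, LT_k)
        perm = np.array([[i, k + i] for i in range(k)]).reshape(-1)
        c_mat = cov_type[np.ix_(perm, perm)]
        return VarianceComponents(
            traits=self.config.traits, C=c_mat, E=self.config.residual_cov.copy()
        )


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeDosage:
    """Hardy-Weinberg dosages with Beta(2,10)+0.01 allele frequencies."""
    v, n = config.n_variants, config.n_individuals
    a, b = config.maf_beta_params
    freq = rng.beta(a, b, size=v) + config.maf_offset
    dosages = rng.binomial(2, freq[:, None], size=(v, n)).astype(np.int8)
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{r + 1}" for r in range(v)],
            "chrom": "1",
            "pos": np.arange(1, v + 1),
            "ref": "A",
            "alt": "B",
            "freq": freq,
        }
    )
    individuals = [f"id{i + 1}" for i in range(n)]
    geno = GenotypeDosage(
        variants[["variant_id", "chrom", "pos", "ref", "alt"]], individuals, dosages
    )
    geno.variants["freq"] = freq
    return geno


def simulate_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Causal and background CS/LT effects for every variant."""
    mu = config.effect_mean()
    sigma = config.effect_cov()
    v = config.n_variants
    effects = rng.multivariate_normal(mu / 1000.0, sigma / 1000.0, size=v)
    causal_idx = rng.choice(v, size=config.n_causal, replace=False)
    effects[causal_idx] = rng.multivariate_normal(mu, sigma, size=config.n_causal)
    causal = np.zeros(v, dtype=bool)
    causal[causal_idx] = True
    cols = [f"beta_{t}" for t in config.traits] + [f"delta_{t}" for t in config.traits]
    truth = pd.DataFrame(effects, columns=cols)
    truth.insert(0, "variant_id", [f"snp{r + 1}" for r in range(v)])
    truth["causal"] = causal
    return truth


def simulate_phenotypes(
    geno: GenotypeDosage,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Phenotypes at baseline and one follow-up visit.

    Returns ``(PhenotypeLong, intervals)`` where ``intervals`` is the
    per-individual follow-up time used by the allele-count filter.
    """
    n, k = config.n_individuals, config.n_traits
    lo, hi = config.time_range_years
    t2 = rng.uniform(lo, hi, size=n)
    covariate = rng.normal(size=n)
    a0, a1, a2 = config.covariate_effects

    g = geno.dosages.astype(np.float64)  # (V, N)
    cols = [f"beta_{t}" for t in config.traits]
    dcols = [f"delta_{t}" for t in config.traits]
    u = g.T @ truth[cols].to_numpy()  # (N, K) level component
    slope = g.T @ truth[dcols].to_numpy()  # (N, K) per-year component
    eps = rng.multivariate_normal(
        np.zeros(k), config.residual_cov, size=(n, 2)
    )  # (N, 2, K), independent across the two visits

    frames = []
    for j, tvec in enumerate([np.zeros(n), t2]):
        vals = (
            a0
            + a1 * tvec[:, None]
            + a2 * covariate[:, None]
            + u
            + slope * tvec[:, None]
            + eps[:, j, :]
        )
        frame = pd.DataFrame(
            {
                "individual_id": np.repeat(geno.individuals, k),
                "trait_id": np.tile(config.traits, n),
                "time": np.repeat(tvec, k),
                "value": vals.reshape(-1),
                "covariate": np.repeat(covariate, k),
            }
        )
        frames.append(frame)
    pheno = PhenotypeLong(pd.concat(frames, ignore_index=True))
    return pheno, t2


def simulate_dataset(config: SimulationConfig, rng) -> SimulatedDataset:
    """Genotypes, effects and phenotypes in one call (seed or Generator)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    geno = simulate_genotypes(config, rng)
    truth = simulate_effects(config, rng)
    pheno, t2 = simulate_phenotypes(geno, truth, config, rng)
    return SimulatedDataset(
        genotypes=geno, phenotypes=pheno, truth=truth, config=config, intervals=t2
    )


def apply_mac_filter(
    geno: GenotypeDosage,
    intervals: np.ndarray,
    min_count: int = 3,
    rule: str = "category",
    individual_ids=None,
) -> np.ndarray:
    """Mask of variants passing the minor-allele-count filter.

    ``rule`` selects how the genotype-by-time requirement is read:

    - ``"category"`` (default): every carrier-genotype x time-interval cell
      (dosage class 1 and 2, intervals binned to the nearest year) must
      contain at least ``min_count`` individuals.
    - ``"dosage_time"``: the folded allele frequency of the dosage x time
      vector must exceed ``min_count / N``.
    - ``"both"``: both requirements.
    """
    if individual_ids is not None:
        dosage = geno.dosage_for(individual_ids)
    else:
        dosage = geno.dosages.astype(float)
    intervals = np.asarray(intervals, dtype=float)
    if dosage.shape[1] != intervals.shape[0]:
        raise ValueError("need one time interval per individual")
    n = intervals.shape[0]
    mask = np.ones(dosage.shape[0], dtype=bool)
    if rule in ("category", "both"):
        years = np.rint(intervals).astype(int)
        for year in np.unique(years):
            in_bin = years == year
            for g_class in (1, 2):
                counts = (dosage[:, in_bin] == g_class).sum(axis=1)
                mask &= counts >= min_count
    if rule in ("dosage_time", "both"):
        weighted = dosage * intervals[None, :]
        freq = weighted.sum(axis=1) / (2.0 * intervals.sum())
        folded = np.minimum(freq, 1.0 - freq)
        mask &= folded > min_count / n
    if rule not in ("category", "dosage_time", "both"):
        raise ValueError(f"unknown MAC rule {rule!r}")
    logger.info(
        "MAC filter (%s, min_count=%d): %d of %d variants pass",
        rule,
        min_count,
        int(mask.sum()),
        len(mask),
    )
    return mask


def inject_missingness(
    pheno: PhenotypeLong,
    fraction: float,
    mode: str,
    target_trait: str,
    rng,
) -> PhenotypeLong:
    """Remove a fraction of one trait's data, reproducibly.

    ``mode="records"`` drops individual measurement rows of the target
    trait; ``mode="individuals"`` removes all of the target trait's records
    for the selected individuals.  Individuals left with no records at all
    are dropped entirely (logged).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if target_trait not in pheno.traits:
        raise ValueError(f"unknown trait {target_trait!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table = pheno.table
    if fraction == 0.0:
        return PhenotypeLong(table)
    target_rows = np.nonzero((table["trait_id"] == target_trait).to_numpy())[0]
    if mode == "records":
        n_drop = int(round(fraction * len(target_rows)))
        drop = rng.choice(target_rows, size=n_drop, replace=False)
    elif mode == "individuals":
        ids = pd.unique(table.iloc[target_rows]["individual_id"])
        n_drop = int(round(fraction * len(ids)))
        chosen = set(rng.choice(ids, size=n_drop, replace=False))
        drop = target_rows[
            table.iloc[target_rows]["individual_id"].isin(chosen).to_numpy()
        ]
    else:
        raise ValueError("mode must be 'records' or 'individuals'")
    kept = table.drop(index=table.index[drop])
    # individuals whose only remaining records lack a baseline, or who lost
    # everything, are removed entirely
    earliest = kept.groupby("individual_id")["time"].min()
    bad = set(earliest[earliest != 0.0].index)
    lost = set(table["individual_id"].unique()) - set(kept["individual_id"].unique())
    if bad or lost:
        logger.info(
            "missingness removed %d individuals entirely (no usable baseline)",
            len(bad | lost),
        )
        kept = kept[~kept["individual_id"].isin(bad)]
    return PhenotypeLong(kept)
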