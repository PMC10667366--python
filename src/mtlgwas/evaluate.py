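"""Power and type-I-error evaluation of the association engine.

A scenario family (longitudinal-to-cross-sectional effect ratios, sample
sizes, or missingness fractions) is run as replicated simulate -> variance
components -> scan -> metrics pipelines.  Power is the fraction of causal
variants detected at the per-replicate Bonferroni threshold, averaged over
traits; type I error is the corresponding fraction among non-causal tested
variants, per effect type.  Variance components are re-estimated by
pairwise AI-REML in each replicate by default; the generating truth can be
substituted for fast runs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .assoc import SnpResults, build_null_system, scan_variants, single_trait_scan
from .design import build_design
from .simulate import (
    SimulationConfig,
    apply_mac_filter,
    inject_missingness,
    simulate_dataset,
)
from .varcomp import estimate_variance_components

__all__ = [
    "bonferroni_threshold",
    "compute_power_type1",
    "run_replicate",
    "run_scenario",
    "compare_se",
    "ScenarioResult",
]

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_tested: int) -> float:
    """Family-wise significance cutoff 0.05 / number of variants tested."""
    if n_tested < 1:
        raise ValueError("no variants were tested")
    return 0.05 / float(n_tested)


def compute_power_type1(results: SnpResults, truth: pd.DataFrame, threshold: float) -> dict:
    """Detection rates at a fixed threshold, per effect type.

    Power averages each trait's causal detection fraction; type I error is
    the fraction of non-causal tested variants called significant.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    tested = (results.variants["filter_status"] == "tested").to_numpy()
    causal = truth["causal"].to_numpy()
    out = {}
    for e, name in enumerate(("cs", "lt")):
        sig = results.p[:, :, e] < threshold  # (V, K)
        pw = sig[tested & causal].mean(axis=0) if (tested & causal).any() else np.array([np.nan])
        t1 = sig[tested & ~causal].mean(axis=0) if (tested & ~causal).any() else np.array([np.nan])
        out[f"power_{name}"] = float(np.nanmean(pw))
        out[f"typeI_{name}"] = float(np.nanmean(t1))
    out["n_tested"] = int(tested.sum())
    out["n_causal_tested"] = int((tested & causal).sum())
    return out


def run_replicate(
    config: SimulationConfig,
    seed: int,
    vc_mode: str = "estimate",
    missing: dict | None = None,
    mac_rule: str = "category",
    mac_min_count: int = 3,
    with_single_trait: bool = False,
    reml_tol: float = 1e-3,
) -> dict:
    """One simulate -> variance components -> scan -> metrics pass.

    ``missing`` is ``{"fraction": f, "mode": "records"|"individuals",
    "trait": name}``; when given and ``with_single_trait`` is set, the
    single-trait comparator is run on the affected trait and its metrics
    and paired standard errors are included.
    """
    rng = np.random.default_rng(seed)
    data = simulate_dataset(config, rng)
    pheno = data.phenotypes
    if missing and missing.get("fraction", 0) > 0:
        pheno = inject_missingness(
            pheno, missing["fraction"], missing["mode"], missing["trait"], rng
        )
    if vc_mode == "estimate":
        # replicated scenario fits use a looser REML tolerance (the variance
        # components are far less precise than the stopping rule either way)
        # and keep the final iterate of a rare slow fit rather than aborting
        vc = estimate_variance_components(
            pheno, ["covariate"], tol=reml_tol, on_nonconvergence="use_last"
        )
    elif vc_mode == "truth":
        vc = data.true_variance_components()
    else:
        raise ValueError("vc_mode must be 'estimate' or 'truth'")

    design = build_design(pheno, ["covariate"])
    mask = apply_mac_filter(
        data.genotypes,
        design.follow_up_interval(),
        min_count=mac_min_count,
        rule=mac_rule,
        individual_ids=design.individuals,
    )
    ns = build_null_system(design, vc)
    results = scan_variants(data.genotypes, ns, tested_mask=mask)
    truth = data.truth.set_index("variant_id").loc[
        results.variants["variant_id"]
    ].reset_index()
    threshold = bonferroni_threshold(
        int((results.variants["filter_status"] == "tested").sum())
    )
    row = {"seed": seed, "threshold": threshold}
    row.update(compute_power_type1(results, truth, threshold))

    if missing and with_single_trait:
        trait = missing["trait"]
        k = results.traits.index(trait)
        tested = (results.variants["filter_status"] == "tested").to_numpy()
        causal = truth["causal"].to_numpy()
        for e, name in enumerate(("cs", "lt")):
            sig = results.p[:, k, e] < threshold
            row[f"joint_power_{name}_{trait}"] = float(sig[tested & causal].mean())
            row[f"joint_typeI_{name}_{trait}"] = float(sig[tested & ~causal].mean())
        single = single_trait_scan(
            pheno, trait, data.genotypes, vc, ["covariate"], tested_mask=mask
        )
        s_tested = (single.variants["filter_status"] == "tested").to_numpy()
        for e, name in enumerate(("cs", "lt")):
            sig = single.p[:, 0, e] < threshold
            row[f"single_power_{name}_{trait}"] = float(sig[s_tested & causal].mean())
            row[f"single_typeI_{name}_{trait}"] = float(sig[s_tested & ~causal].mean())
        pairs, slopes = compare_se(results, single, trait)
        row.update({f"se_slope_{k2}": v for k2, v in slopes.items()})
        row["n_single"] = int(single.n_used[0])
    return row


def compare_se(joint: SnpResults, single: SnpResults, trait: str):
    """Pair joint- and single-analysis standard errors for one trait.

    Returns the paired table and regression-through-origin slopes of joint
    on single SEs per effect type (slope < 1 means the joint analysis is
    more precise).  The two scans must cover the same variants.
    """
    ids_j = list(joint.variants["variant_id"])
    ids_s = list(single.variants["variant_id"])
    if ids_j != ids_s:
        diff = set(ids_j).symmetric_difference(ids_s)
        raise ValueError(f"variant sets differ between scans: {sorted(diff)[:20]}")
    k = joint.traits.index(trait)
    ok = (
        (joint.variants["filter_status"] == "tested").to_numpy()
        & (single.variants["filter_status"] == "tested").to_numpy()
    )
    table = pd.DataFrame(
        {
            "variant_id": np.asarray(ids_j)[ok],
            "se_cs_joint": joint.se[ok, k, 0],
            "se_lt_joint": joint.se[ok, k, 1],
            "se_cs_single": single.se[ok, 0, 0],
            "se_lt_single": single.se[ok, 0, 1],
        }
    )
    slopes = {}
    for name in ("cs", "lt"):
        x = table[f"se_{name}_single"].to_numpy()
        y = table[f"se_{name}_joint"].to_numpy()
        slopes[name] = float((x @ y) / (x @ x))
    return table, slopes


@dataclasses.dataclass
class ScenarioResult:
    label: str
    replicates: pd.DataFrame

    def aggregate(self) -> dict:
        """Means and Monte-Carlo standard errors across replicates."""
        num = self.replicates.select_dtypes(include=[np.number]).drop(
            columns=["seed"], errors="ignore"
        )
        n = len(num)
        out = {"label": self.label, "replicates": n}
        for col in num.columns:
            vals = num[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return out


def run_scenario(
    scenario: dict,
    replicates: int,
    seed: int,
    vc_mode: str = "estimate",
    base_config: SimulationConfig | None = None,
) -> list[ScenarioResult]:
    """Run one scenario family.

    ``scenario`` is one of::

        {"family": "lt_ratio", "lt_values": [1, 5, 20, 50, 100], "n_individuals": 3000}
        {"family": "sample_size", "sizes": [1000, 2000, 3000, 10000], "lt": 5}
        {"family": "missingness", "fractions": [0.15, 0.5],
         "mode": "individuals", "trait": "trait1", "lt": 5, "n_individuals": 3000}

    Replicate r uses seed ``seed + r``; failed replicates are skipped with
    a logged count.
    """
    base = base_config or SimulationConfig()
    family = scenario["family"]
    arms = []
    if family == "lt_ratio":
        for lt in scenario["lt_values"]:
            cfg = dataclasses.replace(
                base,
                lt_attenuation=float(lt),
                n_individuals=scenario.get("n_individuals", base.n_individuals),
            )
            arms.append((f"L={lt}", cfg, None, False))
    elif family == "sample_size":
        for n in scenario["sizes"]:
            cfg = dataclasses.replace(
                base,
                n_individuals=int(n),
                lt_attenuation=float(scenario.get("lt", 5)),
            )
            arms.append((f"n={n}", cfg, None, False))
    elif family == "missingness":
        cfg = dataclasses.replace(
            base,
            lt_attenuation=float(scenario.get("lt", 5)),
            n_individuals=scenario.get("n_individuals", base.n_individuals),
        )
        for frac in scenario["fractions"]:
            missing = {
                "fraction": float(frac),
                "mode": scenario.get("mode", "individuals"),
                "trait": scenario.get("trait", cfg.traits[0]),
            }
            arms.append((f"missing={frac:g}", cfg, missing, True))
    else:
        raise ValueError(f"unknown scenario family {family!r}")

    results = []
    for label, cfg, missing, single in arms:
        rows, failures = [], 0
        n_reps = replicates
        for r in range(n_reps):
            try:
                rows.append(
                    run_replicate(
                        cfg,
                        seed + r,
                        vc_mode=vc_mode,
                        missing=missing,
                        with_single_trait=single,
                    )
                )
            except Exception:  # replicate failure does not stop the family
                failures += 1
                logger.exception("replicate %d of %s failed", r, label)
        if failures:
            logger.warning("%s: %d of %d replicates failed", label, failures, n_reps)
        results.append(ScenarioResult(label=label, replicates=pd.DataFrame(rows)))
    return results
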