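"""Genotype dosage matrix and readers (dosage TSV, VCF)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GenotypeDosage", "read_dosage_tsv", "write_dosage_tsv", "read_vcf"]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


class GenotypeDosage:
    """Dosage matrix (variants x individuals) with variant metadata.

    ``dosages[r, i]`` is the expected alternate-allele count (0..2) of
    individual ``i`` for variant ``r``.  Positions are 1-based as in VCF.
    """

    def __init__(self, variants: pd.DataFrame, individuals, dosages: np.ndarray):
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        dosages = np.asarray(dosages)
        if dosages.shape != (len(variants), len(individuals)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(individuals)} individuals"
            )
        finite = dosages[np.isfinite(dosages.astype(float))]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = variants.reset_index(drop=True)
        self.individuals = [str(s) for s in individuals]
        self.dosages = dosages

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def dosage_for(self, individual_ids) -> np.ndarray:
        """Dosage columns aligned to the given individual ordering (float64)."""
        index = {s: i for i, s in enumerate(self.individuals)}
        try:
            cols = [index[str(s)] for s in individual_ids]
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} has no genotype data") from None
        return self.dosages[:, cols].astype(np.float64)

    def __repr__(self) -> str:
        return f"GenotypeDosage({self.n_variants} variants x {self.n_individuals} individuals)"


def read_dosage_tsv(path) -> GenotypeDosage:
    """Read a variants-by-individuals dosage matrix.

    The first five columns are ``variant_id chrom pos ref alt``; remaining
    column names are individual identifiers.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    individuals = [c for c in table.columns if c not in VARIANT_COLUMNS]
    dosages = table[individuals].to_numpy(dtype=np.float64)
    return GenotypeDosage(table[VARIANT_COLUMNS], individuals, dosages)


def write_dosage_tsv(geno: GenotypeDosage, path) -> None:
    out = geno.variants.copy()
    dos = geno.dosages
    if np.issubdtype(dos.dtype, np.integer) or np.all(dos == np.round(dos)):
        dos = dos.astype(int)
    for i, ind in enumerate(geno.individuals):
        out[ind] = dos[:, i]
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> GenotypeDosage:
    """Read dosages from a VCF, preferring the DS FORMAT field over GT.

    GT genotypes are converted to alternate-allele counts; half-missing or
    missing genotypes become NaN (variants with any missing dosage are
    skipped at scan time).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if "DS" in dict(var.FORMAT or {}) or var.format("DS") is not None:
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except Exception:
                ds = None
        else:
            ds = None
        if ds is None:
            gt = np.asarray(var.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            ds = gt.sum(axis=1)
        rows.append(ds)
        meta.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    dosages = np.vstack(rows) if rows else np.empty((0, len(individuals)))
    return GenotypeDosage(pd.DataFrame(meta, columns=VARIANT_COLUMNS), individuals, dosages)
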