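"""Long-format repeated-measures phenotype container and I/O.

A phenotype table has one row per (individual, trait, time) observation with
the measurement value and any covariates.  Time is expressed in years from
each individual's baseline visit, so every individual's earliest time is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PhenotypeLong", "read_phenotypes", "write_phenotypes"]

REQUIRED_COLUMNS = ("individual_id", "trait_id", "time", "value")


class PhenotypeLong:
    """Validated long-format phenotype table.

    Parameters
    ----------
    table
        DataFrame with columns ``individual_id``, ``trait_id``, ``time``
        (years from baseline), ``value``, plus covariate columns.  Covariates
        that vary over time are simply distinct values per row; covariates
        constant within an individual are repeated on each of their rows.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"phenotype table missing required columns: {missing}")
        table = table.copy()
        table["individual_id"] = table["individual_id"].astype(str)
        table["trait_id"] = table["trait_id"].astype(str)
        table["time"] = table["time"].astype(float)
        table["value"] = table["value"].astype(float)
        self._validate(table)
        self.table = table.reset_index(drop=True)

    @staticmethod
    def _validate(table: pd.DataFrame) -> None:
        if (table["time"] < 0).any():
            bad = table.loc[table["time"] < 0, "individual_id"].iloc[0]
            raise ValueError(f"negative time for individual {bad!r}")
        dup = table.duplicated(subset=["individual_id", "trait_id", "time"])
        if dup.any():
            key = table.loc[dup.idxmax(), ["individual_id", "trait_id", "time"]]
            raise ValueError(
                "duplicate (individual, trait, time) record: "
                f"{tuple(key)}"
            )
        if table["value"].isna().any():
            bad = table.loc[table["value"].isna(), "individual_id"].iloc[0]
            raise ValueError(
                f"missing phenotype value for individual {bad!r}; drop the row "
                "instead of recording NA"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return sorted(self.table["trait_id"].unique())

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.table["individual_id"]))

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_COLUMNS]

    def n_records(self, trait: str) -> int:
        return int((self.table["trait_id"] == trait).sum())

    def restrict_traits(self, traits) -> "PhenotypeLong":
        """Subset to the given traits, dropping individuals left without records."""
        traits = list(traits)
        sub = self.table[self.table["trait_id"].isin(traits)]
        return PhenotypeLong(sub)

    def __repr__(self) -> str:
        return (
            f"PhenotypeLong({len(self.table)} records, "
            f"{len(self.individuals)} individuals, {len(self.traits)} traits)"
        )


def read_phenotypes(path) -> PhenotypeLong:
    """Read a tab-separated long-format phenotype file ('NA' = missing)."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    # rows whose value is NA represent unrecorded measurements
    table = table[~table["value"].isna()]
    return PhenotypeLong(table)


def write_phenotypes(pheno: PhenotypeLong, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, na_rep="NA")
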