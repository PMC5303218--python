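"""Quantitative phenotype/predictor tables (individuals x variables).

Tables are tab-delimited text with individual ids in the first column and
one quantitative variable per remaining column; missing values are encoded
as NA (configurable). An optional map file assigns a chromosome and 1-based
position to variables for region-based testing and Manhattan plots.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable", "read_phenotypes", "read_map"]

DEFAULT_NA_VALUES = ("NA", "na", "NaN", "nan", "-", "")


@dataclass
class PhenotypeTable:
    """Individuals x variables matrix of quantitative measurements.

    Wraps a float DataFrame indexed by individual id. ``positions`` is an
    optional frame indexed by variable name with columns ``chrom`` and
    ``position``.
    """

    data: pd.DataFrame
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate individual ids: {dup}")
        self.data = self.data.astype(float)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self, variable: str) -> np.ndarray:
        return self.data[variable].to_numpy()

    def aligned(self, ids: list[str]) -> pd.DataFrame:
        """Rows reindexed to ``ids`` (absent individuals become missing)."""
        return self.data.reindex(ids)

    def missing_mask(self, variable: str) -> np.ndarray:
        return self.data[variable].isna().to_numpy()

    def position_of(self, variable: str) -> tuple[str, int] | None:
        if self.positions is None or variable not in self.positions.index:
            return None
        row = self.positions.loc[variable]
        return str(row["chrom"]), int(row["position"])

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="iid", na_rep="NA")


def read_phenotypes(
    path: str | Path,
    na_values: tuple[str, ...] = DEFAULT_NA_VALUES,
    positions: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Read a tab-delimited phenotype table (first column: individual id)."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(na_values), keep_default_na=True
    )
    df.index = df.index.astype(str)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    return PhenotypeTable(df, positions=positions)


def read_map(path: str | Path) -> pd.DataFrame:
    """Read a predictor map file: tab-delimited columns name, chrom, position."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: map file needs columns name, chrom, position")
    df = df.iloc[:, :3]
    df.columns = ["name", "chrom", "position"]
    df["position"] = df["position"].astype(int)
    return df.set_index("name")
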