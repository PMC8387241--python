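"""Tabular containers shared across the package.

Count tables are samples x features integer matrices (pandas DataFrame,
sample ids on the index).  Sample metadata is a DataFrame indexed by sample
id with at least the columns ``compartment``, ``host_species``,
``host_genotype``, ``treatment``, ``experiment`` and ``replicate``;
sequential-inoculation samples additionally carry ``first_syncom`` and
``second_syncom`` (which SynCom arrived first/second: "Lj", "At", "mixed"
or "mock").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = (
    "compartment",
    "host_species",
    "host_genotype",
    "treatment",
    "first_syncom",
    "second_syncom",
    "experiment",
    "replicate",
)

__all__ = ["CountTable", "AbundanceTable", "METADATA_COLUMNS", "check_metadata"]


@dataclass
class CountTable:
    """Samples x features matrix of non-negative integer counts.

    ``feature_kind`` records whether columns are SynCom strains or OTUs.
    """

    counts: pd.DataFrame
    feature_kind: str = "strain"

    def __post_init__(self):
        if self.feature_kind not in ("strain", "OTU"):
            raise ValueError("feature_kind must be 'strain' or 'OTU'")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        values = self.counts.to_numpy()
        if values.size:
            if (values < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.feature_kind == other.feature_kind
            and self.counts.equals(other.counts)
        )


@dataclass
class AbundanceTable:
    """Samples x features relative abundances; rows sum to 1.

    Zero-total input samples are kept as all-zero rows and listed in
    ``empty_samples`` so downstream stages can exclude them.
    """

    values: pd.DataFrame
    feature_kind: str = "strain"
    empty_samples: list = field(default_factory=list)

    def __post_init__(self):
        sums = self.values.sum(axis=1).to_numpy()
        nonempty = ~self.values.index.isin(self.empty_samples)
        if len(self.values) and not np.allclose(sums[nonempty], 1.0, atol=1e-9):
            raise ValueError("non-empty abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def drop_empty(self) -> "AbundanceTable":
        keep = ~self.values.index.isin(self.empty_samples)
        return AbundanceTable(self.values.loc[keep], self.feature_kind, [])


def check_metadata(metadata: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Validate that every sample id has exactly one metadata row."""
    if metadata.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return metadata.loc[list(sample_ids)]
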