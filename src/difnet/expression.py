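"""Gene-by-sample expression matrix with per-sample condition labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative normalized expression values (linear scale).

    Parameters
    ----------
    values
        ``genes x samples`` DataFrame; index holds gene ids, columns sample ids.
    conditions
        Mapping from sample id to condition label; must cover every column.
    """

    values: pd.DataFrame
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = self.values
        if not vals.index.is_unique:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dupes}")
        if not vals.columns.is_unique:
            raise InputError("duplicate sample ids")
        arr = vals.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise InputError("expression values must be numeric")
        if np.isnan(arr).any():
            raise InputError("expression matrix contains missing values")
        if arr.size and arr.min() < 0:
            raise InputError("expression values must be nonnegative")
        missing = [s for s in vals.columns if s not in self.conditions]
        if missing:
            raise InputError(f"samples without a condition label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition_labels(self) -> list[str]:
        """Distinct condition labels in first-seen (column) order."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.conditions[s], None)
        return list(seen)

    def samples_for(self, label: str) -> list[str]:
        """Sample ids carrying `label`, in column order."""
        out = [s for s in self.values.columns if self.conditions[s] == label]
        if not out:
            raise InputError(
                f"condition label {label!r} not present "
                f"(available: {self.condition_labels})"
            )
        return out

    def submatrix(self, genes) -> pd.DataFrame:
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise InputError(f"genes absent from matrix: {missing}")
        return self.values.loc[genes]

    def merge(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Column-wise union of two matrices over the shared gene set.

        Gene sets must be identical; sample ids must be disjoint.
        """
        if list(self.values.index) != list(other.values.index):
            raise InputError("cannot merge matrices with differing gene ids")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise InputError(f"sample ids present in both matrices: {sorted(overlap)}")
        values = pd.concat([self.values, other.values], axis=1)
        conditions = dict(self.conditions)
        conditions.update(other.conditions)
        return ExpressionMatrix(values=values, conditions=conditions)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and dict(self.conditions) == dict(
            other.conditions
        )
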