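"""Core in-memory containers shared across pipeline stages.

Matrices are pandas DataFrames throughout: probes on the rows, samples on
the columns, so a stage can always be checked against the TSV it writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six leukocyte populations of the reference-based deconvolution.
CELL_TYPES = ("granulocytes", "monocytes", "b_cells", "nk_cells", "cd4t", "cd8t")

VALID_SCALES = ("beta", "M", "residual")


class ValidationError(ValueError):
    """Raised when an input matrix or table violates its contract."""


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values on a declared scale.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
    scale
        One of ``"beta"`` (fractions in [0, 1]), ``"M"`` (log2 ratios) or
        ``"residual"`` (covariate-residualized M-values).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if not self.values.index.is_unique:
            raise ValidationError("duplicate probe ids")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("matrix contains missing or non-finite values")
        if self.scale == "beta" and arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValidationError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[probe_ids], scale=self.scale)


def as_cell_proportions(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x cell-types fraction table and return it.

    Each fraction must lie in [0, 1] and each row must sum to at most 1
    (a small tolerance absorbs round-off from the constrained solver).
    """
    missing = [c for c in CELL_TYPES if c not in frame.columns]
    if missing:
        raise ValidationError(f"cell proportion table missing columns: {missing}")
    arr = frame[list(CELL_TYPES)].to_numpy()
    if (arr < -1e-9).any() or (arr > 1.0 + 1e-9).any():
        raise ValidationError("cell fractions outside [0, 1]")
    if (arr.sum(axis=1) > 1.0 + 1e-6).any():
        raise ValidationError("cell fractions sum above 1")
    return frame[list(CELL_TYPES)]
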