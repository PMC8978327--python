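"""Expression-matrix container shared across the pipeline.

The study design has four ordered developmental stages of bone-marrow B
cells; every matrix in the pipeline is transcripts x stages in a single
normalized unit (RPM for circRNAs, TPM for miRNAs, FPKM for mRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four bone-marrow B-cell developmental stages, in developmental order.
STAGES: tuple[str, ...] = ("pro-B", "pre-B", "immature", "mature")

#: Normalized expression units accepted per omics layer.
UNITS: tuple[str, ...] = ("RPM", "TPM", "FPKM", "counts")


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values, transcripts x ordered stages.

    Parameters
    ----------
    data
        DataFrame with transcript ids as the index and stage labels as
        columns, in stage order.
    unit
        One of ``RPM``, ``TPM``, ``FPKM`` or ``counts``.
    """

    data: pd.DataFrame
    unit: str = "RPM"
    lengths: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if values.size and np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at transcript "
                f"{self.data.index[r]!r}, stage {self.data.columns[c]!r}"
            )

    @property
    def transcripts(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_transcripts(self) -> int:
        return self.data.shape[0]

    def require_four_stages(self) -> None:
        """Raise unless the matrix carries exactly the four study stages."""
        if tuple(self.data.columns) != STAGES:
            raise ValueError(
                f"expected stage columns {STAGES}, got {tuple(self.data.columns)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.unit == other.unit and self.data.equals(other.data)
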