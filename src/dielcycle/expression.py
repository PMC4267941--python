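"""The gene x timepoint expression container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import SamplingLayout


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values (FPKM-like) with a sampling layout.

    ``values`` is a genes x samples DataFrame whose columns follow the
    layout's ordering (all points of day 1, then day 2, ...).
    """

    values: pd.DataFrame
    layout: SamplingLayout

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.layout.n_points:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but layout "
                f"expects {self.layout.n_points}"
            )
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def day_average(self) -> pd.DataFrame:
        """Average the appended days per ZT; columns are ZT bin labels."""
        arr = self.to_array()
        ppd = self.layout.points_per_day
        folded = arr.reshape(self.n_genes, self.layout.n_days, ppd).mean(axis=1)
        return pd.DataFrame(folded, index=self.gene_ids, columns=self.layout.zt_bins())
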