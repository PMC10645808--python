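"""Gene-level count matrix container for the expression comparators."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with annotations.

    Attributes
    ----------
    counts:
        Integer counts, genes as rows, samples as columns.
    sample_meta:
        Per-sample annotations indexed by sample name (e.g. ``truth_class``
        for tumour samples or ``role``/``patient_id`` for enriched/PBMC
        pairs).
    gene_sets:
        Named gene sets (``signature_epithelial``, ``signature_mesenchymal``).
    gene_markers:
        ``{gene: panel marker}`` for genes that proxy a panel antibody.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    gene_markers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        sets = list(self.gene_sets.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if set(sets[i]) & set(sets[j]):
                    raise ValueError("gene sets must be disjoint")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CountMatrix":
        return cls(pd.read_csv(path, index_col=0), **kwargs)
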