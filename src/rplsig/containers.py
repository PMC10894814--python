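"""Core in-memory containers shared across the pipeline.

Expression data travel as a genes-by-samples matrix with a declared scale
(``linear`` or ``log2p1``); signatures are two disjoint gene arms with the
derivation parameters that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "log2p1")

#: Macrodissected biopsy region codes: tumour core, tumour stroma,
#: invasive front, non-malignant region.
REGION_CODES = ("TC", "TS", "IF", "NR")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale
        ``"linear"`` (non-negative) or ``"log2p1"`` (log2(x+1)).
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (log2p1 inputs back-transformed as 2**x - 1)."""
        if self.scale == "linear":
            return self
        lin = np.exp2(self.values) - 1.0
        # guard against -eps from float round-off at x = 0
        lin = lin.clip(lower=0.0)
        return ExpressionMatrix(lin, scale="linear")

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2p1")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], scale=self.scale)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class Signature:
    """The two signature arms plus the parameters that derived them.

    ``rp_high`` are genes higher in the poor-outcome (rapid progressor) arm,
    ``ls_high`` in the good-outcome (long survivor) arm.
    """

    rp_high: list[str]
    ls_high: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rp_high = list(dict.fromkeys(self.rp_high))
        self.ls_high = list(dict.fromkeys(self.ls_high))
        overlap = set(self.rp_high) & set(self.ls_high)
        if overlap:
            raise ValueError(f"signature arms overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> list[str]:
        return self.rp_high + self.ls_high

    def to_gene_sets(self) -> list[GeneSet]:
        return [
            GeneSet("RP_HIGH", "genes higher in rapid progressors", list(self.rp_high)),
            GeneSet("LS_HIGH", "genes higher in long survivors", list(self.ls_high)),
        ]

    @classmethod
    def from_gene_sets(cls, sets, params: dict | None = None) -> "Signature":
        by_name = {s.name.upper(): s for s in sets}
        if "RP_HIGH" not in by_name or "LS_HIGH" not in by_name:
            raise ValueError("expected gene sets named RP_HIGH and LS_HIGH")
        return cls(list(by_name["RP_HIGH"].genes), list(by_name["LS_HIGH"].genes), params or {})


@dataclass
class CellTypeReference:
    """Per-cell-type mean expression over a gene universe (linear scale)."""

    mean_expression: pd.DataFrame  # genes x cell types
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.mean_expression.shape[1] == 0:
            raise ValueError("reference has no cell types")
        if (self.mean_expression.to_numpy() < 0).any():
            raise ValueError("reference means must be non-negative")
        # case-fold cell-type labels for exact-string matching across sources
        self.mean_expression = self.mean_expression.rename(columns=lambda c: str(c).casefold())
        if self.mean_expression.columns.has_duplicates:
            raise ValueError("duplicate cell-type labels after case-folding")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expression.columns)
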