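"""Cell-type-of-origin assignment for signature genes.

A gene's candidate origin in one reference is the cell type with the
highest mean expression, accepted only when that mean is at least
``ratio_threshold`` times the runner-up (specificity).  A gene is assigned
an origin only when two independent references agree on the same accepted
top type — a transparent consensus stand-in for digital cytometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CellTypeReference, Signature


def top_type(
    gene: str, reference: CellTypeReference, ratio_threshold: float = 2.0
) -> tuple[str | None, float]:
    """Most specific cell type for one gene in one reference.

    Returns ``(cell_type, ratio)`` where ratio = top mean / second mean;
    ``(None, ratio)`` when the ratio is below threshold, the top is tied,
    or the gene is absent.
    """
    if gene not in reference.mean_expression.index:
        return None, float("nan")
    means = reference.mean_expression.loc[gene].to_numpy(dtype=float)
    types = reference.cell_types
    if len(types) < 2:
        return (types[0], float("inf")) if means[0] > 0 else (None, float("nan"))
    order = np.argsort(means)[::-1]
    top, second = means[order[0]], means[order[1]]
    if top == second:
        return None, 1.0
    ratio = float("inf") if second == 0 else float(top / second)
    if ratio < ratio_threshold:
        return None, ratio
    return types[order[0]], ratio


def consensus_assign(
    signature: Signature,
    ref1: CellTypeReference,
    ref2: CellTypeReference,
    ratio_threshold: float = 2.0,
) -> pd.DataFrame:
    """Assign each signature gene an origin supported by both references.

    Returns a table with gene_id, arm, per-reference top type and ratio,
    and assigned_type ('unassigned' unless both references accept the same
    type).  Symmetric in the two references; raising the threshold never
    assigns a previously unassigned gene.
    """
    shared = set(ref1.cell_types) & set(ref2.cell_types)
    if not shared:
        raise ValueError(
            f"references share no cell-type labels: {ref1.cell_types} vs {ref2.cell_types}"
        )
    rows = []
    arms = [("rp_high", g) for g in signature.rp_high] + [
        ("ls_high", g) for g in signature.ls_high
    ]
    for arm, gene in arms:
        t1, r1 = top_type(gene, ref1, ratio_threshold)
        t2, r2 = top_type(gene, ref2, ratio_threshold)
        assigned = t1 if (t1 is not None and t1 == t2) else "unassigned"
        rows.append(
            {
                "gene_id": gene,
                "arm": arm,
                "top_ref1": t1 or "none",
                "ratio_ref1": r1,
                "top_ref2": t2 or "none",
                "ratio_ref2": r2,
                "assigned_type": assigned,
            }
        )
    return pd.DataFrame(rows)


def origin_counts(assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type counts of assigned genes in each arm (the barplot data)."""
    return (
        assignment.groupby(["assigned_type", "arm"]).size().unstack(fill_value=0).reset_index()
    )
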