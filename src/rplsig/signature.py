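"""Two-group differential expression and signature derivation.

The signature rule: a gene joins the poor-outcome ("rp_high") arm when its
linear-scale group-mean fold change is >= fc_threshold with a two-sided
rank-sum p < p_threshold, and the good-outcome ("ls_high") arm when the
fold change is <= 1/fc_threshold at the same p.  Fold changes use group
means of linear expression with a 1e-9 pseudo-guard in both numerator and
denominator; no multiple-testing correction enters membership (nominal p),
but Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSet, Signature

log = logging.getLogger("rplsig")

_FC_EPS = 1e-9


def rank_sum_test(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method="auto"`` uses the exact null distribution when the combined
    sample size is <= 12 and the data are tie-free, otherwise the normal
    approximation with tie and continuity correction.  ``"exact"`` and
    ``"asymptotic"`` force a path; exact with ties is refused.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    if method == "auto":
        method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        raise ValueError("exact rank-sum path requires tie-free data")
    if method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(combined) == 0:
        return 1.0  # all observations identical
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def welch_t_test(x, y) -> float:
    """Two-sided Welch t-test p-value (Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def over_representation(query: GeneSet, pathway: GeneSet, universe) -> tuple[float, int]:
    """Hypergeometric upper-tail over-representation test.

    Returns ``(p, overlap)`` where p = P(overlap >= observed) when drawing
    ``len(query)`` genes from the universe containing ``len(pathway)``
    pathway members.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q = set(query.genes) & universe
    p_set = set(pathway.genes) & universe
    if set(query.genes) - universe or set(pathway.genes) - universe:
        log.warning("query/pathway genes outside the universe were dropped")
    overlap = len(q & p_set)
    if len(q) == 0:
        return 1.0, 0
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(p_set), len(q)))
    return min(p, 1.0), overlap


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def derive_signature(
    expr: ExpressionMatrix,
    labels: pd.DataFrame,
    group_a: str | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[Signature, pd.DataFrame]:
    """Derive the two-arm signature from a labelled cohort.

    ``labels`` needs columns sample_id and group with exactly two levels,
    each covering >= 2 matrix samples; ``group_a`` names the poor-outcome
    level (default: first level in sorted order).  Returns the signature
    and the full per-gene table (fold_change, p_value, q_value, direction).
    """
    lab = labels.set_index("sample_id")["group"]
    lab = lab.loc[[s for s in expr.sample_ids if s in lab.index]]
    levels = sorted(lab.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if group_a is None:
        group_a = levels[0]
    group_b = [l for l in levels if l != group_a][0]
    a_samples = lab.index[lab == group_a].tolist()
    b_samples = lab.index[lab == group_b].tolist()
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")

    lin = expr.to_linear().values
    xa = lin[a_samples].to_numpy()
    xb = lin[b_samples].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)

    both_tiny = (mean_a < _FC_EPS) & (mean_b < _FC_EPS)
    if both_tiny.any():
        warnings.warn(
            f"{int(both_tiny.sum())} genes with both group means < {_FC_EPS} excluded",
            stacklevel=2,
        )
    fc = (mean_a + _FC_EPS) / (mean_b + _FC_EPS)

    n_total = xa.shape[1] + xb.shape[1]
    constant = np.ptp(np.hstack([xa, xb]), axis=1) == 0
    if n_total <= 12:
        pvals = np.array(
            [
                1.0 if constant[i] else rank_sum_test(xa[i], xb[i], method="auto")
                for i in range(lin.shape[0])
            ]
        )
    else:
        with np.errstate(invalid="ignore"):
            pvals = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided",
                                       method="asymptotic").pvalue
        pvals = np.where(constant, 1.0, pvals)
    qvals = bh_qvalues(pvals)

    up = (fc >= fc_threshold) & (pvals < p_threshold) & ~both_tiny
    down = (fc <= 1.0 / fc_threshold) & (pvals < p_threshold) & ~both_tiny
    direction = np.where(up, "A_high", np.where(down, "B_high", "none"))

    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "fold_change": fc,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
        }
    )
    params = {
        "fc_threshold": fc_threshold,
        "p_threshold": p_threshold,
        "test": "wilcoxon_rank_sum",
        "fc_statistic": "linear_group_means",
        "group_a": str(group_a),
        "group_b": str(group_b),
    }
    gene_arr = np.array(expr.gene_ids, dtype=object)
    sig = Signature(list(gene_arr[up]), list(gene_arr[down]), params)
    return sig, table
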