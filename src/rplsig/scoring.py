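"""RPLS scoring: per-sample raw scores, cohort z-scores, median-split calls,
origin-restricted subset scores, per-cell rank scores, cross-cohort
projection and the arm-anticorrelation diagnostic.

The raw score of a sample is log2(sum of linear expression over the
poor-outcome arm + 1) - log2(sum over the good-outcome arm + 1); scores are
then standardized within a cohort (sample SD, ddof=1).  Higher scores mean
a more chemoresistant-like profile.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSet, Signature
from .signature import rank_sum_test

log = logging.getLogger("rplsig")

#: scoring errors out below this per-arm signature coverage
DEFAULT_MIN_COVERAGE = 0.5


def _arm_coverage(expr: ExpressionMatrix, signature: Signature, min_coverage: float):
    present = set(expr.gene_ids)
    rp = [g for g in signature.rp_high if g in present]
    ls = [g for g in signature.ls_high if g in present]
    cov_rp = len(rp) / len(signature.rp_high) if signature.rp_high else 0.0
    cov_ls = len(ls) / len(signature.ls_high) if signature.ls_high else 0.0
    for arm, genes, cov in (("rp_high", rp, cov_rp), ("ls_high", ls, cov_ls)):
        if not genes:
            raise ValueError(f"no {arm} signature genes present in the matrix")
        if cov < min_coverage:
            raise ValueError(
                f"{arm} coverage {cov:.2f} below minimum {min_coverage:.2f}"
            )
    if cov_rp < 1.0 or cov_ls < 1.0:
        log.warning("signature coverage: rp=%.2f ls=%.2f", cov_rp, cov_ls)
    return rp, ls, cov_rp, cov_ls


def rpls_raw(
    expr: ExpressionMatrix,
    signature: Signature,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-sample arm sums and raw score.

    Returns a DataFrame with sample_id, sum_rp, sum_ls, raw_score,
    coverage_rp, coverage_ls; raw_score = log2(sum_rp+1) - log2(sum_ls+1).
    """
    rp, ls, cov_rp, cov_ls = _arm_coverage(expr, signature, min_coverage)
    lin = expr.to_linear().values
    sum_rp = lin.loc[rp].sum(axis=0)
    sum_ls = lin.loc[ls].sum(axis=0)
    raw = np.log2(sum_rp + 1.0) - np.log2(sum_ls + 1.0)
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "sum_rp": sum_rp.to_numpy(),
            "sum_ls": sum_ls.to_numpy(),
            "raw_score": raw.to_numpy(),
            "coverage_rp": cov_rp,
            "coverage_ls": cov_ls,
        }
    )


def zscore(raw_scores) -> np.ndarray:
    """Cohort z-scores (mean 0, sample SD 1 with ddof=1).

    A single sample cannot be self-standardized (use reference-cohort mode);
    a zero-variance cohort yields all-zero z with a warning.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.size < 2:
        raise ValueError(
            "z-scoring needs >= 2 samples; standardize against a reference cohort instead"
        )
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate cohort: all raw scores equal; z set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def classify_by_median(z_scores) -> np.ndarray:
    """Median-split calls: 'high' iff strictly greater than the cohort median.

    Scores equal to the median go 'low' (strict reading of "> median").
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size < 2:
        raise ValueError("median split needs >= 2 samples")
    med = np.median(z)
    calls = np.where(z > med, "high", "low")
    if (calls == "low").all():
        warnings.warn("all scores <= median (ties); every sample called low", stacklevel=2)
    return calls


def score_table(
    expr: ExpressionMatrix,
    signature: Signature,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Full per-sample score table: raw score, cohort z-score and median call."""
    tab = rpls_raw(expr, signature, min_coverage=min_coverage)
    tab["z_score"] = zscore(tab["raw_score"].to_numpy())
    tab["call"] = classify_by_median(tab["z_score"].to_numpy())
    return tab[
        ["sample_id", "sum_rp", "sum_ls", "raw_score", "z_score", "call",
         "coverage_rp", "coverage_ls"]
    ]


def subset_score(
    expr: ExpressionMatrix,
    signature: Signature,
    origin_filter: str,
    origins: pd.DataFrame,
    min_coverage: float = 0.0,
) -> pd.DataFrame:
    """Score with arms restricted to genes assigned to one cellular origin.

    ``origins`` is a consensus assignment table (gene_id, assigned_type);
    ``origin_filter`` keeps only genes assigned to that (case-folded) type.
    Errors if the filter empties an arm, listing the genes that survived.
    """
    if origin_filter is None or origin_filter == "all":
        return score_table(expr, signature, min_coverage=DEFAULT_MIN_COVERAGE)
    want = str(origin_filter).casefold()
    assigned = origins.loc[
        origins["assigned_type"].astype(str).str.casefold() == want, "gene_id"
    ]
    keep = set(assigned)
    rp = [g for g in signature.rp_high if g in keep]
    ls = [g for g in signature.ls_high if g in keep]
    if not rp or not ls:
        raise ValueError(
            f"origin filter {origin_filter!r} empties an arm "
            f"(surviving rp_high={rp}, ls_high={ls})"
        )
    sub = Signature(rp, ls, dict(signature.params, origin_filter=want))
    tab = score_table(expr, sub, min_coverage=min_coverage)
    tab.attrs["arm_sizes"] = {"rp_high": len(rp), "ls_high": len(ls)}
    return tab


def cell_rank_score(cell_values, gene_ids, signature: Signature) -> float:
    """Mean-normalized-rank score of one cell, in (-1, 1).

    All G genes are ranked by ascending expression with mid-ranks for ties,
    normalized as r = (rank - 0.5) / G; the score is mean(r over the
    poor-outcome arm) - mean(r over the good-outcome arm).  Invariant to any
    monotone transform of the cell's expression.  Returns NaN (flagged) if
    either arm is absent from the cell's gene universe.
    """
    values = np.asarray(cell_values, dtype=float)
    idx = {g: i for i, g in enumerate(gene_ids)}
    rp = [idx[g] for g in signature.rp_high if g in idx]
    ls = [idx[g] for g in signature.ls_high if g in idx]
    if not rp or not ls:
        return float("nan")
    r = (stats.rankdata(values, method="average") - 0.5) / values.size
    return float(r[rp].mean() - r[ls].mean())


def cell_score_table(
    counts: pd.DataFrame, annotations: pd.DataFrame, signature: Signature
) -> pd.DataFrame:
    """Per-cell rank scores plus the raw-sum score, with annotations attached.

    ``counts`` is genes x cells; cells whose arms are undetectable get NaN
    and are excluded downstream.
    """
    genes = list(counts.index)
    idx = {g: i for i, g in enumerate(genes)}
    rp = [idx[g] for g in signature.rp_high if g in idx]
    ls = [idx[g] for g in signature.ls_high if g in idx]
    arr = counts.to_numpy(dtype=float)
    if rp and ls:
        ranks = stats.rankdata(arr, axis=0, method="average")
        r = (ranks - 0.5) / arr.shape[0]
        rank_score = r[rp].mean(axis=0) - r[ls].mean(axis=0)
        raw = np.log2(arr[rp].sum(axis=0) + 1.0) - np.log2(arr[ls].sum(axis=0) + 1.0)
    else:
        rank_score = np.full(arr.shape[1], np.nan)
        raw = np.full(arr.shape[1], np.nan)
    out = annotations.copy().reset_index(drop=True)
    out["rank_score"] = rank_score
    out["raw_score"] = raw
    return out


def annotate_rp_like_bulk(
    raw_scores, reference_mean: float | None = None, reference_sd: float | None = None
) -> pd.DataFrame:
    """RP-like / LS-like calls for bulk samples or cell lines.

    Reference mode standardizes each raw score against a reference cohort's
    mean/SD; self-cohort mode z-scores within the cohort.  RP-like iff the
    standardized score is > 0.
    """
    x = np.asarray(raw_scores, dtype=float)
    if reference_mean is None and reference_sd is None:
        std = zscore(x)
    else:
        if reference_mean is None or reference_sd is None or reference_sd <= 0:
            raise ValueError("reference mode needs both a mean and a positive SD")
        std = (x - reference_mean) / reference_sd
    return pd.DataFrame(
        {"standardized": std, "call": np.where(std > 0, "RP-like", "LS-like")}
    )


def annotate_rp_like_cells(cell_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-patient RP-like / LS-like annotation from per-cell rank scores.

    Patient summary = median cell rank_score; RP-like iff the summary
    exceeds the cohort median of summaries.  Each patient also gets a
    two-sided rank-sum p of its cells' scores against all other patients'
    cells.
    """
    ok = cell_scores.dropna(subset=["rank_score"])
    summaries = ok.groupby("patient_id")["rank_score"].median()
    if len(summaries) < 2:
        raise ValueError("need >= 2 patients for a cohort median split")
    med = summaries.median()
    rows = []
    for patient, summary in summaries.items():
        own = ok.loc[ok["patient_id"] == patient, "rank_score"].to_numpy()
        rest = ok.loc[ok["patient_id"] != patient, "rank_score"].to_numpy()
        p = rank_sum_test(own, rest, method="asymptotic") if len(own) >= 2 and len(rest) >= 2 else float("nan")
        rows.append(
            {
                "patient_id": patient,
                "median_rank_score": summary,
                "call": "RP-like" if summary > med else "LS-like",
                "p_vs_rest": p,
            }
        )
    return pd.DataFrame(rows)


def _spearman(x, y, n_exact: int = 9) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= n_exact, else t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= n_exact:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def arm_summaries(expr: ExpressionMatrix, signature: Signature) -> pd.DataFrame:
    """Per-sample mean-normalized expression of each signature arm.

    Each arm gene's log2(x+1) profile is centred across samples; the arm
    summary is the per-sample mean of these centred profiles.
    """
    logm = expr.to_log2p1().values
    out = {}
    for arm, genes in (("rp", signature.rp_high), ("ls", signature.ls_high)):
        present = [g for g in genes if g in logm.index]
        if not present:
            raise ValueError(f"no {arm}_high genes present")
        sub = logm.loc[present]
        out[arm] = (sub.sub(sub.mean(axis=1), axis=0)).mean(axis=0)
    return pd.DataFrame({"rp_summary": out["rp"], "ls_summary": out["ls"]})


def anticorrelation_diagnostic(
    expr: ExpressionMatrix, signature: Signature
) -> tuple[float, float]:
    """Spearman correlation across samples between the two arm summaries.

    In cohorts where one latent programme drives both arms with opposite
    signs, this is strongly negative (the signature's defining diagnostic).
    Exact permutation p for n <= 9, t-approximation otherwise.
    """
    if expr.n_samples < 4:
        raise ValueError("anticorrelation diagnostic needs >= 4 samples")
    summ = arm_summaries(expr, signature)
    return _spearman(summ["rp_summary"].to_numpy(), summ["ls_summary"].to_numpy())


def geometric_mean_score(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Cytolytic-style per-sample score: exp(mean(ln(x+1))) - 1 over the set."""
    lin = expr.to_linear().values
    present = [g for g in gene_set.genes if g in lin.index]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    logs = np.log(lin.loc[present] + 1.0)
    return np.exp(logs.mean(axis=0)) - 1.0


def rank_auc(scores, labels, positive) -> float:
    """Rank-AUC of ``scores`` for separating ``labels == positive`` from the rest."""
    s = np.asarray(scores, dtype=float)
    mask = np.asarray(labels) == positive
    pos, neg = s[mask], s[~mask]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    r = stats.rankdata(s)
    u = r[mask].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
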