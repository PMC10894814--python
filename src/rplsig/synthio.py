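"""Synthetic cohort generators with planted ground truth.

Emulates the statistical structure the analysis assumes so that every
downstream step can be tested against known truth:

* bulk cohorts — log-normal baseline expression, two anticorrelated gene
  programmes driven by one shared per-sample latent activity whose mean
  differs between two outcome groups, multiplicative library-size factors;
* survival tables — exponential event times whose hazard is proportional
  to the standardized latent activity, administratively censored;
* single-cell counts — overdispersed (gamma-Poisson) counts over several
  cell types with a planted subset of signature genes expressed
  predominantly in the myeloid compartment;
* paired cell-type references — two mean-expression tables with a
  configurable fraction of genes given concordant top cell types;
* a cell-line panel whose drug sensitivity correlates negatively with the
  planted programme activity.

Randomness: one root seed per config; each component draws from its own
``default_rng([seed, offset])`` sub-stream, so adding a component never
shifts existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellTypeReference, ExpressionMatrix, Signature

# fixed sub-stream offsets (never reorder; append only)
_BASELINE, _LATENT, _NOISE, _LIBSIZE, _SURVIVAL, _SC, _REFS, _LINES = range(8)


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


@dataclass
class SyntheticCohortConfig:
    """Design of a two-group bulk cohort with planted programmes.

    Defaults mirror the extreme-outlier biopsy design the pipeline was
    built around: 7 poor-outcome vs 6 good-outcome samples, 2000 genes
    with 100-gene programmes planted in each direction.
    """

    n_group_a: int = 7
    n_group_b: int = 6
    n_genes: int = 2000
    n_rp_high: int = 100
    n_ls_high: int = 100
    effect_log2fc: float = 2.0
    program_coupling: float = 1.0
    noise_sd: float = 0.5
    libsize_cv: float = 0.2
    latent_sd: float = 0.75
    true_beta: float = math.log(1.7)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_genes", "n_rp_high", "n_ls_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rp_high + self.n_ls_high > self.n_genes:
            raise ValueError("programme genes exceed n_genes")
        if not 0.0 <= self.program_coupling <= 1.0:
            raise ValueError("program_coupling must lie in [0, 1]")
        if self.noise_sd < 0 or self.libsize_cv < 0 or self.latent_sd < 0:
            raise ValueError("noise_sd, libsize_cv and latent_sd must be >= 0")
        if self.effect_log2fc != 0 and (self.n_group_a == 0 or self.n_group_b == 0):
            raise ValueError("an effect requires both groups to be non-empty")


@dataclass
class SyntheticTruth:
    """Planted truth of a bulk cohort, for recovery testing."""

    gene_membership: dict  # gene_id -> "rp_high" | "ls_high" | "null"
    latent_activity: dict  # sample_id -> float
    true_beta: float
    group_label: dict  # sample_id -> "A" | "B"

    def __post_init__(self) -> None:
        acts = np.array(list(self.latent_activity.values()), dtype=float)
        if acts.size and not np.isfinite(acts).all():
            raise ValueError("latent activities must be finite")

    def arm_genes(self, arm: str) -> list[str]:
        return [g for g, m in self.gene_membership.items() if m == arm]

    def to_json_dict(self) -> dict:
        return {
            "gene_membership": self.gene_membership,
            "latent_activity": self.latent_activity,
            "true_beta": self.true_beta,
            "group_label": self.group_label,
        }


def generate_bulk_cohort(config: SyntheticCohortConfig):
    """Simulate a two-group bulk cohort.

    Returns ``(ExpressionMatrix (linear), annotation DataFrame, SyntheticTruth)``.

    Per-gene baseline log2 mean ~ Normal(5, 2). One shared latent activity
    a_i ~ Normal(mu_group, latent_sd) with the group means separated by
    ``effect_log2fc`` loads on the poor-outcome ("rp_high") arm with
    coefficient +program_coupling and on the good-outcome ("ls_high") arm
    with -program_coupling; null genes are unaffected.  Log2-scale residual
    noise and multiplicative log-normal library factors are then applied
    and the matrix is exponentiated to linear scale.
    """
    cfg = config
    n = cfg.n_group_a + cfg.n_group_b
    sample_ids = [f"A{i:03d}" for i in range(cfg.n_group_a)] + [
        f"B{i:03d}" for i in range(cfg.n_group_b)
    ]
    groups = ["A"] * cfg.n_group_a + ["B"] * cfg.n_group_b
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    rng_base = _rng(cfg.seed, _BASELINE)
    baseline = rng_base.normal(5.0, 2.0, size=cfg.n_genes)
    membership = np.array(["null"] * cfg.n_genes, dtype=object)
    programme_idx = rng_base.choice(cfg.n_genes, size=cfg.n_rp_high + cfg.n_ls_high, replace=False)
    membership[programme_idx[: cfg.n_rp_high]] = "rp_high"
    membership[programme_idx[cfg.n_rp_high:]] = "ls_high"
    loading = np.where(membership == "rp_high", 1.0, np.where(membership == "ls_high", -1.0, 0.0))

    mu = np.where(np.array(groups) == "A", cfg.effect_log2fc / 2.0, -cfg.effect_log2fc / 2.0)
    latent = mu + _rng(cfg.seed, _LATENT).normal(0.0, cfg.latent_sd, size=n)

    log2_expr = (
        baseline[:, None]
        + cfg.program_coupling * loading[:, None] * latent[None, :]
        + _rng(cfg.seed, _NOISE).normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    )
    if cfg.libsize_cv > 0:
        sigma = math.sqrt(math.log1p(cfg.libsize_cv**2))
        factors = _rng(cfg.seed, _LIBSIZE).lognormal(-sigma**2 / 2.0, sigma, size=n)
    else:
        factors = np.ones(n)
    linear = np.exp2(log2_expr) * factors[None, :]

    expr = ExpressionMatrix(pd.DataFrame(linear, index=gene_ids, columns=sample_ids), "linear")
    ann = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    truth = SyntheticTruth(
        gene_membership=dict(zip(gene_ids, membership)),
        latent_activity=dict(zip(sample_ids, latent.astype(float))),
        true_beta=cfg.true_beta,
        group_label=dict(zip(sample_ids, groups)),
    )
    return expr, ann, truth


def generate_survival(
    truth: SyntheticTruth,
    baseline_hazard: float,
    censor_time: float,
    seed: int,
    true_beta: float | None = None,
) -> pd.DataFrame:
    """Exponential survival times with hazard proportional to the latent score.

    hazard_i = baseline_hazard * exp(beta * z_i) with z the cohort-standardized
    latent activity; administrative censoring at ``censor_time``.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    beta = truth.true_beta if true_beta is None else float(true_beta)
    samples = list(truth.latent_activity)
    act = np.array([truth.latent_activity[s] for s in samples], dtype=float)
    if not np.isfinite(act).all():
        raise ValueError("latent activities must be finite")
    sd = act.std(ddof=1) if len(act) > 1 else 0.0
    z = (act - act.mean()) / sd if sd > 0 else np.zeros_like(act)
    hazard = baseline_hazard * np.exp(beta * z)
    raw = _rng(seed, _SURVIVAL).exponential(1.0, size=len(samples)) / hazard
    event = (raw <= censor_time).astype(int)
    time = np.minimum(raw, censor_time)
    return pd.DataFrame(
        {"sample_id": samples, "time": time, "event": event, "latent_z": z}
    )


@dataclass
class SyntheticSingleCellConfig:
    """Design of a multi-cell-type single-cell count simulation."""

    n_patients: int = 3
    cells_per_patient: int = 200
    cell_type_proportions: dict = field(
        default_factory=lambda: {"tumour": 0.4, "myeloid": 0.3, "t_cell": 0.2, "fibroblast": 0.1}
    )
    n_myeloid_signature_genes: int = 13
    depth_mean: float = 2000.0
    dispersion: float = 0.5
    n_background_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.cells_per_patient < 0:
            raise ValueError("counts must be >= 0")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        if any(p < 0 for p in self.cell_type_proportions.values()):
            raise ValueError("proportions must be >= 0")


def generate_single_cell(config: SyntheticSingleCellConfig, signature: Signature):
    """Simulate gamma-Poisson single-cell counts over several cell types.

    Gene universe = signature genes + background genes.  The first
    ``n_myeloid_signature_genes`` signature genes (alternating between the
    two arms) are planted as myeloid-predominant: their mean is boosted in
    myeloid cells and suppressed elsewhere.  Returns
    ``(counts DataFrame genes x cells, cell annotation DataFrame, planted myeloid genes)``.
    """
    if not signature.genes:
        raise ValueError("signature is empty")
    types = list(config.cell_type_proportions)
    if "myeloid" not in types and config.n_myeloid_signature_genes > 0:
        raise ValueError("cell_type_proportions must include 'myeloid' to plant myeloid genes")
    sig_genes = list(signature.genes)
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    genes = sig_genes + bg_genes

    # alternate arms so a myeloid origin-filter keeps both arms populated
    rp, ls = list(signature.rp_high), list(signature.ls_high)
    planted: list[str] = []
    i = 0
    while len(planted) < config.n_myeloid_signature_genes and (i < len(rp) or i < len(ls)):
        if i < len(rp):
            planted.append(rp[i])
        if len(planted) < config.n_myeloid_signature_genes and i < len(ls):
            planted.append(ls[i])
        i += 1

    rng = _rng(config.seed, _SC)
    n_cells = config.n_patients * config.cells_per_patient
    if n_cells == 0:
        counts = pd.DataFrame(np.zeros((len(genes), 0), dtype=int), index=genes)
        ann = pd.DataFrame(columns=["cell_id", "patient_id", "cell_type"])
        return counts, ann, planted

    patient = np.repeat([f"P{i:02d}" for i in range(config.n_patients)], config.cells_per_patient)
    probs = np.array([config.cell_type_proportions[t] for t in types])
    cell_type = rng.choice(types, size=n_cells, p=probs / probs.sum())

    # relative per-gene baseline, shared across cell types, mildly variable by type
    base_rel = rng.lognormal(0.0, 1.0, size=len(genes))
    type_effect = rng.lognormal(0.0, 0.3, size=(len(genes), len(types)))
    mean_by_type = base_rel[:, None] * type_effect
    planted_mask = np.isin(genes, planted)
    myeloid_col = types.index("myeloid") if "myeloid" in types else None
    if myeloid_col is not None:
        for j in range(len(types)):
            scale = 10.0 if j == myeloid_col else 0.1
            mean_by_type[planted_mask, j] *= scale
    # normalize each type's profile so expected depth = depth_mean
    mean_by_type = mean_by_type / mean_by_type.sum(axis=0, keepdims=True) * config.depth_mean

    type_index = np.array([types.index(t) for t in cell_type])
    mu = mean_by_type[:, type_index]  # genes x cells
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam)

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    ann = pd.DataFrame({"cell_id": cell_ids, "patient_id": patient, "cell_type": cell_type})
    return pd.DataFrame(counts, index=genes, columns=cell_ids), ann, planted


def generate_two_references(
    genes,
    cell_types=("tumour", "myeloid", "t_cell", "fibroblast"),
    concordant_fraction: float = 1.0,
    specificity: float = 8.0,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Two per-cell-type mean-expression references over a shared gene universe.

    A fraction of genes get the same clearly-dominant top cell type in both
    references (concordant); the rest get different top types (discordant),
    so a two-reference consensus leaves them unassigned.  Returns
    ``(ref1, ref2, truth DataFrame)`` where truth records each gene's
    planted type per reference and whether it is concordant.
    """
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must lie in [0, 1]")
    genes = list(genes)
    types = [str(t).casefold() for t in cell_types]
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    rng = _rng(seed, _REFS)
    n = len(genes)
    n_conc = int(round(concordant_fraction * n))
    concordant = np.zeros(n, dtype=bool)
    concordant[rng.choice(n, size=n_conc, replace=False)] = True

    top1 = rng.integers(0, len(types), size=n)
    top2 = top1.copy()
    for i in np.flatnonzero(~concordant):
        choices = [j for j in range(len(types)) if j != top1[i]]
        top2[i] = rng.choice(choices)

    def build(tops, source):
        base = rng.lognormal(0.0, 0.2, size=(n, len(types)))
        base[np.arange(n), tops] *= specificity
        base *= rng.lognormal(0.0, noise_sd, size=base.shape)
        df = pd.DataFrame(base, index=genes, columns=types)
        return CellTypeReference(df, source_id=source)

    ref1 = build(top1, "synthetic_ref_1")
    ref2 = build(top2, "synthetic_ref_2")
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "type_ref1": [types[i] for i in top1],
            "type_ref2": [types[i] for i in top2],
            "concordant": concordant,
        }
    )
    return ref1, ref2, truth


def generate_cell_line_panel(
    signature: Signature,
    n_lines: int = 25,
    n_null_genes: int = 500,
    activity_sd: float = 1.0,
    sensitivity_noise_sd: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Cell-line expression panel with drug sensitivity tied to programme activity.

    Each line gets a latent programme activity a ~ Normal(0, activity_sd)
    loading +a on the poor-outcome arm and -a on the good-outcome arm; drug
    sensitivity = -a + noise, so high-activity (chemoresistant-like) lines
    are less sensitive.  Returns ``(ExpressionMatrix, panel DataFrame)``
    with per-line activity and sensitivity.
    """
    rng = _rng(seed, _LINES)
    genes = list(signature.genes) + [f"N{i:04d}" for i in range(n_null_genes)]
    loading = np.array(
        [1.0] * len(signature.rp_high) + [-1.0] * len(signature.ls_high) + [0.0] * n_null_genes
    )
    baseline = rng.normal(5.0, 2.0, size=len(genes))
    activity = rng.normal(0.0, activity_sd, size=n_lines)
    log2_expr = (
        baseline[:, None]
        + loading[:, None] * activity[None, :]
        + rng.normal(0.0, noise_sd, size=(len(genes), n_lines))
    )
    line_ids = [f"CL{i:02d}" for i in range(n_lines)]
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_expr), index=genes, columns=line_ids), "linear"
    )
    sensitivity = -activity + rng.normal(0.0, sensitivity_noise_sd, size=n_lines)
    panel = pd.DataFrame(
        {"line_id": line_ids, "activity": activity, "drug_sensitivity": sensitivity}
    )
    return expr, panel
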