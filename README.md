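# rplsig

Tools for deriving and using a two-arm chemoresistance expression signature
in liver-cancer transcriptomics, built around the extreme-outlier cohort
design: patients with comparable baseline characteristics who diverge on
chemotherapy as rapid progressors (RP, survival under ~6 months) or long
survivors (LS, over ~23 months). Pretreatment biopsy transcriptomes from
such a cohort define an "RP-high" and an "LS-high" gene arm; the resulting
per-sample score is a candidate metric of innate chemoresistance in
intrahepatic cholangiocarcinoma and other liver tumours.

The package is aimed at computational biologists who want to derive,
stress-test or project this kind of signature: every analysis step is a
library function, every step is exercised against a bundled synthetic
cohort generator with planted ground truth, and the numbered scripts under
`analysis/` walk through the full study on simulated data.

## The model

**Derivation.** For each gene, the two outcome groups are compared by a
two-sided Wilcoxon rank-sum test and a linear-scale fold change of group
means, FC = (mean_RP + ε)/(mean_LS + ε). A gene joins the RP-high arm when
FC ≥ 2 and p < 0.05, and the LS-high arm when FC ≤ 1/2 at the same p.

**Scoring.** A sample's raw RPLS score is

    raw = log2(Σ RP-high expression + 1) − log2(Σ LS-high expression + 1)

on the linear scale, z-scored within the cohort (sample SD, ddof = 1).
Samples are stratified as score-high (> cohort median) or score-low.
Because one latent programme drives the two arms with opposite signs,
their per-sample summaries are strongly anticorrelated — a diagnostic the
package computes (Spearman, exact permutation p at small n).

**Downstream.** Signature genes are assigned cellular origins only when
two independent single-cell references agree on the same specific top cell
type (max-mean with a ×2 specificity ratio); origin-restricted subset
scores (e.g. myeloid-only) use the same formula. Per-cell scoring uses a
mean-normalized-rank statistic invariant to monotone transforms. Outcome
associations are quantified with Kaplan–Meier curves, log-rank tests, Cox
proportional-hazards models (Newton on the Breslow/Efron partial
likelihood, per-SD hazard ratios) and AIC backward elimination.

**Synthetic cohorts.** The generator plants: log-normal baseline
expression; one shared latent activity per sample whose group means differ
by a configurable log2 effect and which loads +/− on the two arms
(producing the anticorrelation rather than assuming it); log2-scale noise;
multiplicative library-size factors; exponential survival with hazard
proportional to the standardized latent score; overdispersed multi-cell-type
single-cell counts with planted myeloid-predominant signature genes; and a
cell-line panel whose drug sensitivity tracks programme activity.

## Worked example

```python
from rplsig import (SyntheticCohortConfig, generate_bulk_cohort,
                    derive_signature, score_table, anticorrelation_diagnostic)

cfg = SyntheticCohortConfig(seed=2026)      # 7 vs 6 samples, 2000 genes
expr, labels, truth = generate_bulk_cohort(cfg)
sig, de = derive_signature(expr, labels, group_a="A")
scores = score_table(expr, sig)
rho, p = anticorrelation_diagnostic(expr, sig)
```

Running `python analysis/02_derive_signature.py` and
`python analysis/03_score_and_classify.py` on this cohort prints:

```
derived arms: rp_high=100, ls_high=85
planted-gene recovery: 183/200 (91.5%)
null genes in signature: 2
raw-score rank-AUC (poor vs good outcome): 0.952
arm anticorrelation: Spearman rho = -0.934 (p = 3e-06)
cell lines called RP-like: 12/25
drug sensitivity RP-like vs LS-like: medians -0.86 vs 0.81, rank-sum p = 0.000101
```

meaning: of the 200 planted programme genes the 7-vs-6 screen recovered
183 with only 2 false entries; the raw score almost perfectly ranks
poor-outcome above good-outcome samples; the two arms anticorrelate
strongly across biopsies; and projecting the signature onto a simulated
cell-line panel marks 12/25 lines RP-like, which are significantly less
drug-sensitive — the behaviour the signature is designed to capture.

A command-line interface mirrors the library
(`rplsig simulate|derive|score|origins|survival|run-all`), e.g.

```sh
rplsig run-all --seed 7 --out out/
```

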