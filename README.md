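# fdtox

QSAR assessment of aquatic-toxicity-related protein binding of fullerene
derivatives (FDs): descriptor computation, SMILES-fragment Monte-Carlo
optimal descriptors (DCW), counter-propagation neural networks (CPANN),
multiple linear regression over 12 protein binding-score responses,
leverage-based applicability domains, and structural-alert screening —
with a seeded synthetic-table generator standing in for the study's
compound table so the entire pipeline is testable offline.

## The problem

Functionalized C60 cages reach the aquatic environment through wastewater.
At environmentally realistic (sub-EC50) concentrations, toxicity is driven
by binding to specific proteins; docking-style binding scores of an FD
against human proteins with close orthologues in fish and amphibians — and
against acetylcholinesterase, a canonical aquatic-toxicity target — serve
as a computable toxicity surrogate. This package models those scores from
structure so new FDs can be prioritized without docking:

* **Responses** (consumed as data, never computed): the average binding
  score over a large protein panel, the best-complex binding affinity, and
  scores for ten PDB proteins (1D6U, 1E3K, 1GOS, 1GS4, 1H82, 1OG5, 1UOM,
  2F9Q, 2J0D, 3ERT), optionally TcAChE (1VOT).
* **Predictors**: topological diameter TD, polarizability volume QPpolrz,
  25 drug-like descriptors, and the optimal descriptor
  DCW(m) = Σ_k count_k(m)·CW(A_k), whose correlation weights CW are tuned
  by seeded Monte-Carlo hill climbing to maximize |r(DCW, y)| on the
  training set.
* **Models**: a six-entry registry — regression and CPANN on all 28
  descriptors (exploratory), and regression/CPANN on (QPpolrz, TD) or DCW
  (predictive) — evaluated per response on a recorded train/test split,
  with R²/Q² (squared Pearson), a PRESS-based Q² variant, RMSE, and
  leave-one-out Q²cv for the CPANN models.
* **Reliability screens**: Williams-plot applicability domain
  (h = x'(X'X)⁻¹x, h* = 3(p+1)/n, ±3σ residual bounds) and a local SMARTS
  library of 14 aquatic-toxicity structural alerts with shipped
  positive/negative controls.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
python analysis/01_generate_dataset.py --seed 1
python analysis/02_response_correlations.py
python analysis/03_fit_optimal_descriptor.py --seed 1
python analysis/04_model_registry.py --seed 1
python analysis/05_applicability_domain.py
python analysis/06_alerts_and_prioritization.py
```

With seed 1 the generated table has 169 compounds (127 train / 42 test;
average score mean 5788, range 3776–7542). The drivers print, among other
things:

```
protein scores vs average score: r = 0.593 .. 0.936
         model  r2_train  q2_test
  regression_1    0.9398   0.9299
       cpann_1    0.9760   0.9114
CPANN model 1 LOO-CV on the average score: Q^2cv = 0.9177, RMSEcv = 216.4
regression 1: h* = 0.0709; 6 structural outliers (h > h*), 1 response outliers
160/169 compounds carry >= 1 aquatic-toxicity alert; 3 high-scoring
alert-free compounds flagged for review
```

Reading: the ten protein scores track the panel-average score closely
(r up to 0.94), so the average score is a usable unifying response; the
two-descriptor regression explains ~94 % of its training variance and
predicts the held-out split at Q² ≈ 0.93; the 14×14 CPANN matches it and
cross-validates at Q²cv ≈ 0.92; six compounds sit outside the leverage
domain of the two-descriptor model; and nearly every decorated cage carries
at least one structural alert, while three high-scoring compounds with no
alert are flagged for manual review instead of being cleared. All tables
land in `results/`.

The same pipeline is scriptable (`fdtox run-all --seed 1 --out-dir out/`)
and each stage has a CLI subcommand (`generate`, `featurize`, `dcw`,
`train`, `ad`, `alerts`, `report`).

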