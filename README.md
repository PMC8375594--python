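# mcinet

Graph-theoretic brain-network features and nested cross-validated SVM
classification for predicting conversion from mild cognitive impairment
(MCI) to Alzheimer's disease (AD).

## The problem

MCI patients split into non-converters (MCInc) and converters (MCIc, who
progress to AD within ~36 months). Separating the two groups — and
separating converters from manifest AD — from baseline imaging is a
small-sample, high-dimensional classification problem: a few dozen
subjects against more than a thousand candidate biomarkers derived from
structural MRI morphometry and resting-state fMRI connectivity.

`mcinet` implements the full analysis framework for ROI-level inputs:

1. **Networks.** A structural *thickness-similarity* network over the 68
   Desikan–Killiany cortical regions, `w(i,j) = exp(−(CTᵢ−CTⱼ)²/α)` with
   α = 0.01, and a functional network of Fisher z-transformed Pearson
   correlations between 90 AAL-region BOLD time series, in three bands
   (full 0.01–0.08 Hz, slow-4 0.027–0.08 Hz, slow-5 0.01–0.027 Hz).
   Both are thresholded to binary graphs at a connection *cost* — the
   retained fraction of all V(V−1)/2 edges — swept over 8–44% in 1% steps.
2. **Features.** Per subject and cost, a fixed 1150-slot vector:
   204 raw morphometry values (thickness, volume, area), 136
   structural-network nodal metrics (degree ND, path length NL), and 810
   functional nodal metrics (NL, ND, betweenness BC × 3 bands), with a
   bidirectional index codec.
3. **Selection.** Three algorithms behind one sklearn transformer
   interface: random subset feature selection (RSFS) with a
   dummy-feature null, greedy minimal-redundancy-maximal-relevance
   (mRMR) on mutual information, and stability selection over
   L1-penalized regression (SS-LR) on the λ ∈ (0.05, 0.3) grid.
4. **Classification.** Leave-one-out outer cross-validation with
   normalization and selection fitted inside each training fold; an
   RBF-SVM `K(x₁,x₂) = exp(−‖x₁−x₂‖²/σ²)` tuned by an inner stratified
   10-fold grid search over C, σ ∈ {4⁻⁴ … 4⁴}; random-forest, KNN and
   AdaBoost comparators; up-/down-sampling protocols.
5. **Statistics.** Accuracy/sensitivity/specificity with exact
   Clopper–Pearson 95% CIs, balanced accuracy BAC = (SEN+SPE)/2, ROC/AUC
   with DeLong variance-based CIs, and exact McNemar comparisons.

Because the underlying patient data are access-controlled, the package
ships a synthetic-cohort generator (`mcinet.cohort`) that emulates the
post-preprocessing inputs: configurable group sizes, planted standardized
atrophy effects on chosen regions, and band-limited multivariate time
series whose latent correlation structure differs between groups on
chosen node sets. Every downstream stage is tested against it.

## Worked example

```python
import numpy as np
from mcinet import (CohortConfig, NestedCVConfig, build_design_matrix,
                    default_conversion_effects, generate_cohort, nested_cv,
                    report_from_folds)

struct_eff, conn_eff = default_conversion_effects("MCIc")
config = CohortConfig(n_per_group={"MCInc": 40, "MCIc": 40}, seed=7,
                      struct_effect=struct_eff, conn_effect=conn_eff)
cohort = generate_cohort(config)

fm = build_design_matrix(cohort, ("MCInc", "MCIc"), cost=0.19)
folds = nested_cv(fm.values, fm.y, NestedCVConfig(selector="rsfs", top_k=10, seed=11))
rep = report_from_folds(folds)
print(f"ACC {100*rep.acc:.2f}%  SEN {100*rep.sen:.2f}%  "
      f"SPE {100*rep.spe:.2f}%  BAC {100*rep.bac:.2f}%  AUC {rep.auc:.3f}")
```

Output:

```
ACC 80.00%  SEN 75.00%  SPE 85.00%  BAC 80.00%  AUC 0.921
```

Each of the 80 subjects was held out once; in every fold the remaining 79
subjects were z-scored, RSFS ranked all 1150 features on them alone, and
a grid-tuned RBF-SVM on the top 10 features predicted the held-out
subject. The AUC of 0.92 shows the pipeline recovering the planted
medial-temporal atrophy (≈1 SD) and hippocampal–temporal–thalamic
connectivity weakening (−0.35 correlation units) that
`default_conversion_effects` injects into the converter group; with
permuted labels the same pipeline sits at chance.

A thin CLI covers the common batch path:

```bash
mcinet simulate --seed 1 --out cohort/ --n-per-group "MCInc=55,MCIc=30,AD=19"
mcinet run --config run.yaml --cohort cohort/ --out results/
```

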