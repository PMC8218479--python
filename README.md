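# abequant

Semi-quantitative T1-weighted MRI analysis for detecting **acute bilirubin
encephalopathy (ABE)** in neonates with hyperbilirubinemia — implemented as a
fully synthetic, end-to-end testable pipeline.

## The problem

Severe neonatal hyperbilirubinemia can progress to ABE when bilirubin enters
the basal ganglia. On T1-weighted images both ABE and non-ABE
hyperbilirubinemia patients may show hyperintensity in the globus pallidus
(GP) and subthalamic nucleus (STN), so visual radiological reading separates
the two groups poorly. A simple, scanner-robust alternative scores each
patient by normalized ROI intensities on the axial slice with the largest
GP+STN coverage:

```
GP_norm  = mean(GP)  / mean(WM)
STN_norm = mean(STN) / mean(WM)
```

where WM is an anterior subcortical white-matter reference region. An
operating cutoff on the score is chosen by maximizing the Youden index
J = sensitivity + specificity − 1 over the ROC curve.

Because no public dataset exists for this problem, the package ships a
**phantom cohort generator** that emulates the study's statistical structure
(47 ABE vs 32 non-ABE subjects; GP_norm 1.39 ± 0.06 vs 1.33 ± 0.06; STN_norm
1.47 ± 0.09 vs 1.42 ± 0.07; clinical covariates; 18-slice axial stacks) and
renders 2D T1-like slices with ROI label masks. Everything downstream — ROI
quantification, ROC/Youden analysis, diagnostic metrics, rater agreement,
cohort statistics, and a desk-scale residual-CNN classification protocol with
class activation mapping — runs on these phantoms.

## Who this is for

Researchers evaluating semi-quantitative intensity markers or small-scale
CNN baselines on neuroimaging classification problems, and anyone needing a
self-contained, reproducible reference implementation of ROC/Youden cutoff
selection and the surrounding evaluation statistics.

## Worked example

```python
import numpy as np
from abequant import (PhantomConfig, generate_cohort, feature_table_from_stacks,
                      roc_curve, auc, youden_cutoff, classify, confusion, metrics)

config = PhantomConfig(seed=7)          # 47 ABE vs 32 non-ABE, study defaults
records, stacks = generate_cohort(config)
features = feature_table_from_stacks(stacks, {r.subject_id: r.group for r in records})

curve = roc_curve(features["gp_norm"], features["label"])
cut = youden_cutoff(curve)
print(f"AUC (GP_norm):      {auc(curve):.4f}")
print(f"Youden cutoff:      {cut.cutoff:.4f}  (J = {cut.j:.4f})")

predicted = classify(features["gp_norm"], cut.cutoff)
ms = metrics(confusion(predicted, features["label"].to_numpy()), auc=auc(curve))
for name, value in ms.display().items():
    print(f"{name:<12} {value}")
```

Output:

```
AUC (GP_norm):      0.7620
Youden cutoff:      1.3519  (J = 0.4747)
sensitivity  78.70%
specificity  68.80%
precision    78.72%
f1           78.72%
accuracy     74.68%
auc          76.20%
```

One 79-subject phantom cohort gives an AUC near the binormal value
Φ(0.06/√(2·0.06²)) ≈ 0.76 implied by the configured group distributions, and
a Youden cutoff near the midpoint of the group means (1.36); the in-sample
metrics at that cutoff are optimistic by the usual resubstitution bias.

The same workflow is available from the shell:

```bash
abequant generate --out data/ --seed 7
abequant quantify --data data/ --out features.csv
abequant roc --features features.csv --score gp_norm
abequant evaluate --features features.csv --cutoff cutoff.json
abequant cohort-stats --table data/cohort.csv
abequant train-cnn --data data/ --out runs/
```

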