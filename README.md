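# mesfda — minimum-entropy-set anomaly detection for functional data

`mesfda` flags anomalous curves — outliers in magnitude or in shape — in a
sample of functional data observed on a common time grid: growth curves,
mortality-rate profiles by age, sensor traces, any setting where each
observation is a discretely sampled function.

## Method

The package treats entropy as the organizing notion for abnormality.

1. **Representation.** Each curve is smoothed by Gaussian-kernel ridge
   regression, `(γmI + K)a = y` with `K_{kl} = exp(-σ(t_k - t_l)²)`, and
   projected onto the leading eigenvectors of the Gram matrix:
   `z_j = λ_j Σ_i a_i v_{ij}`, `j = 1…d`. The sample of curves becomes an
   `n × d` matrix of truncated Karhunen–Loève-type scores.
2. **Entropy.** The Rényi α-entropy of the score distribution is estimated
   parametrically (Gaussian plug-in, closed form
   `H_α = (d/2)ln 2π + ½ ln det Σ + (d/2) ln(α)/(α−1)`, Shannon limit at
   α = 1) or locally via `h_i = exp(mean distance of z_i to its k nearest
   neighbours)`.
3. **Detection.** A ν-minimum-entropy set — equivalently a high-density set
   of mass 1−ν — is estimated either as a robust Mahalanobis ellipsoid
   `(z−μ̂)ᵀΣ̂⁻¹(z−μ̂) ≤ c` (parametric, "PA") or by thresholding the local
   entropies at ρ*, the `⌈(1−ν)n⌉`-th smallest training value, which solves
   the associated linear program in closed form (non-parametric, "NPA").
   Curves outside the set are anomalies.

Estimators follow scikit-learn conventions (`KernelCurveRepresenter` is a
transformer; `ParametricMESDetector` / `NonParametricMESDetector` are
outlier detectors with `fit` / `predict` returning ±1) and compose with
`sklearn.pipeline.Pipeline`. See `docs/methods.md` for assumptions,
parameter meanings and numerical conventions.

## Worked example

```python
import numpy as np
from mesfda import (ScenarioSpec, simulate_scenario, detect_anomalies,
                    confusion_metrics, auc_roc, kernel_entropy, KernelSpec)

sample = simulate_scenario(ScenarioSpec(scenario="C", n=400, nu=0.10, seed=42))
result = detect_anomalies(sample, method="pa", nu=0.10,
                          threshold_mode="empirical", seed=42)
cm = confusion_metrics(sample.labels, result.labels)
print(f"flagged {result.flagged.size} curves  (d = {result.settings['d']})")
print(f"TPR = {cm.tpr:.1f}%   TNR = {cm.tnr:.2f}%   "
      f"aROC = {auc_roc(result.scores, sample.labels):.2f}%")
print(f"Shannon kernel entropy of the sample: "
      f"{kernel_entropy(sample, KernelSpec(10, 0.15)).value:.3f} nats")
```

prints

```
flagged 40 curves  (d = 7)
TPR = 85.0%   TNR = 98.33%   aROC = 97.88%
Shannon kernel entropy of the sample: 4.815 nats
```

The sample holds 400 curves on 50 grid points, 10% of them contaminated
half with magnitude outliers (inflated level and spread) and half with
shape outliers (different harmonic mix). With ν known, the empirical
threshold flags exactly ν·n = 40 curves; here 34 of the 40 true outliers
are among them (TPR 85%), 6 normal curves are flagged by mistake
(TNR 98.33%), and the Mahalanobis score separates the classes with
aROC ≈ 98%.

The same steps are available from the shell:

```sh
mesfda simulate --scenario C --n 400 --nu 0.10 --seed 42 --with-labels --output curves.csv
mesfda detect --input curves.csv --has-labels --method pa --nu 0.10 --seed 42 --output result.json
mesfda mc-table --scenarios A,B,C --nus 0.10 --m-reps 100 --seed 1 --output table.csv
```

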