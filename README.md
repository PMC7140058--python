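# fwrecur

Free-water-suppressed diffusion-tensor analysis of peritumoral edema, as a
reusable, fully tested pipeline running on synthetic glioblastoma cohorts.

Most glioblastoma recurrences arise in the peritumoral edema, but
diffusion metrics there are contaminated by free water: fractional
anisotropy (FA) collapses wherever edema fluid dominates the voxel, hiding
the microstructural damage that tumor infiltration causes. This package
implements the full analysis chain that addresses this:

1. **Synthetic cohorts** — a geometric glioblastoma phantom (tumor core,
   edema shell with a recurrence-destined sector, white matter) with known
   per-voxel tissue tensors and tissue-volume fractions, forward-simulated
   through the two-compartment signal model
   `S_k = S0 [ f exp(-b_k g_k' D g_k) + (1-f) exp(-b_k d_free) ]`
   with Rician noise (default: 32 directions at b = 800 s/mm², one b = 0,
   2 mm isotropic, SNR 30).
2. **ANN free-water elimination** — a small fully connected network
   (N_b → N_b/2 → N_b/4 → 1, bounded output) trained on synthetic signals
   with known f estimates the tissue-volume fraction per voxel; the
   isotropic free-water compartment is then removed algebraically from the
   measured attenuations.
3. **Robust tensor metrics** — log-linear weighted least squares with
   RESTORE-style iterative outlier rejection; FA and MD maps from both the
   uncorrected and the free-water-corrected (FWC) signals, with a
   noise-moment correction of FA's eigenvalue-repulsion bias.
4. **ROI statistics** — per-patient 10th/50th/90th percentiles and means
   per region, compared across the cohort with Wilcoxon's rank-sum test
   (recurrence edema vs pure edema; tissue volume / MD / FA, corrected
   and uncorrected).
5. **Recurrence prediction** — random 3×3×3 patches from both edema
   classes, random-intercept logistic models (patient as random effect,
   adaptive Gauss–Hermite marginal ML), grouped threefold
   cross-validation, ROC curves, and DeLong's test for correlated AUCs.

The science, the model assumptions and all numerical choices are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Run the whole pipeline on a 10-patient synthetic cohort:

```sh
fwrecur all --seed 42 --out demo_run
```

which simulates the cohort, trains the fraction network, corrects the
signals, fits tensors, and prints the report (abridged):

```
Edema-with-recurrence vs pure edema (rank-sum p-values):
   tissue_fraction   p50  FWC: p=0.52052
                MD   p50  FWC: p=0.08897
                MD   p90  FWC: p=0.00033 *
                MD   p90  raw: p=0.67758
                FA   p50  raw: p=0.01133 *
                FA   p50  FWC: p=0.00018 *
                FA   p90  raw: p=0.00033 *
                FA   p90  FWC: p=0.00018 *

Cross-validated AUC (FWC-FA):        0.981
Cross-validated AUC (uncorrected FA): 0.794
DeLong comparison: z=3.702, p=0.00021
```

Reading it: estimated tissue-volume fractions do not separate the two
edema compartments (all p > 0.5), mean diffusivity separates them only
after free-water correction and mainly in the upper percentile, while FA
separates them in every summary statistic — far more decisively after
free-water suppression. Downstream, a recurrence classifier built on
FWC-FA patches reaches a cross-validated AUC of 0.98 against 0.79 for
uncorrected FA, and DeLong's test confirms the difference (p = 2·10⁻⁴).
On synthetic cohorts the free-water masking and the tissue-FA deficit are
planted by construction; the point of the example is that the pipeline
recovers exactly this structure from the noisy signal.

Each stage can also be run separately (`fwrecur simulate|train|correct|
metrics|roistats|predict --config cfg.yaml --out DIR`); stages verify
their inputs against SHA-256 checksums in the run manifest, and identical
configurations reproduce byte-identical outputs.

## Library use

```python
from fwrecur import (make_scheme, simulate_cohort, make_training_set,
                     train_fraction_estimator)
from fwrecur.pipeline import analyze_cohort

scheme = make_scheme(32, 800.0, 1, seed=7)
estimator = train_fraction_estimator(make_training_set(scheme, 50_000, seed=1), seed=2)
cohort = simulate_cohort(8, scheme, snr=30.0, seed=0)
result = analyze_cohort(cohort, estimator, seed=0)
print(result["auc_fwc"], result["auc_uncorrected"], result["delong"].p_value)
```

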