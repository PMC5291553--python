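# ivimnac

Segmented IVIM-DWI fitting and treatment-response statistics for
longitudinal tumor imaging, built around the breast neoadjuvant
chemotherapy (NAC) monitoring setting.

## The problem

Pathologic complete response (pCR) to NAC strongly predicts outcome in
locally advanced breast cancer, but only a minority of patients achieve
it. Multi-b diffusion-weighted MRI, analysed with the intravoxel
incoherent motion (IVIM) model, separates slow tissue-water diffusion
from fast capillary pseudo-diffusion and can probe treatment effects
(falling cellularity, vascular regression) weeks before tumor size
changes. This package provides the full analysis chain for that kind of
study: the signal model, the voxel-wise segmented fitter, ROI and
Δ-parameter measures, the response-prediction statistics, and synthetic
phantoms/cohorts so every stage is testable without patient data.

## The model

The IVIM signal at diffusion weighting `b` (s/mm²) is biexponential:

```
S(b) = S0 · [ f · exp(−b·D*) + (1 − f) · exp(−b·D) ]
```

with `D` the true diffusion coefficient (mm²/s), `D*` the
pseudo-diffusion coefficient of the perfusion pool (typically ≥ 10×D),
`f` the perfusion fraction of the b = 0 signal, and `S0` the unweighted
signal. Estimation is **segmented**: because the perfusion term vanishes
for `b > 200 s/mm²`, `D` (and an initial `f`) come from an ordinary
least-squares line on `ln S` vs `b` over the high-b points
({400, 800, 1000} in the default 12-b scheme); `D*` (with `f` and `S0`
refined) then comes from a bound-constrained damped least-squares fit of
the full decay with `D` held fixed, under the identifiability constraint
`D* ≥ D`. Downstream, pre-minus-mid parameter changes (Δ-parameters) are
compared between responder groups (normality-routed Student t /
Mann-Whitney), ranked by ROC AUC with Hanley–McNeil confidence
intervals, operated at Youden-optimal cutoffs with exact Clopper–Pearson
CIs on sensitivity/specificity/PPV/NPV, and correlated with mass
shrinkage by Spearman rank correlation.

## Worked example

Fit a noiseless decay generated from a known parameter triple (the
pre-treatment values of a responding tumor):

```python
from ivimnac import IVIMParams, forward_signal, fit_voxel

truth = IVIMParams(D=0.906e-3, D_star=40.4e-3, f=0.357, S0=1000.0)
decay = forward_signal(truth)          # default 12-b scheme, 0..1000 s/mm^2
fit = fit_voxel(decay).params
print(f"D  = {fit.D*1e3:.3f} x 1e-3 mm^2/s")
print(f"D* = {fit.D_star*1e3:.1f} x 1e-3 mm^2/s")
print(f"f  = {fit.f*100:.1f} %")
```

prints

```
D  = 0.906 x 1e-3 mm^2/s
D* = 40.4 x 1e-3 mm^2/s
f  = 35.7 %
```

i.e. the segmented two-stage fit returns the generating diffusion
coefficient, pseudo-diffusion coefficient and perfusion fraction on the
conventional reporting scales. The same machinery runs voxel-wise over
4D volumes (`fit_parameter_maps`), and the cohort layer turns per-patient
pre/mid tables into a full statistics report (`run_full_analysis`).

A shell workflow is available too:

```bash
ivimnac simulate-phantom --out-dir ph --seed 1            # synthetic 4D DWI
ivimnac fit-maps --volume ph/dwi.nii.gz --bval ph/dwi.bval \
    --mask ph/mask.nii.gz --out-dir maps                   # D/D*/f NIfTI maps
ivimnac simulate-cohort --out cohort.csv --seed 1          # 9 + 19 patients
ivimnac analyze --cohort cohort.csv --out report.json      # full statistics
```

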