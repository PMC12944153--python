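# fluvopbpk

Population physiologically based pharmacokinetic (PBPK) simulation of
**fluvoxamine**, built to study how **CYP2D6 metabolizer phenotype** and
**aging** combine to shape drug exposure — and what that implies for dosing
the drug in elderly patients against its therapeutic trough window of
60–230 ng/mL.

The package is aimed at pharmacometricians and PK modelers who want a
transparent, scriptable alternative to proprietary population simulators for
this class of question: every virtual subject, clearance term and ODE state
is inspectable, and every study run is a pure function of a config and a
seed.

## The model

**Virtual subjects.** Younger-adult (18–65 y) and geriatric (65–98 y)
populations are generated with demographics (uniform age, Bernoulli sex,
sex-specific truncated-normal weight), hepatic physiology (liver mass and
hepatic blood flow scaling allometrically with body size and declining
linearly with age above 40 y; log-normal MPPGL, mean 40 mg/g, CV 30%), and
log-normal CYP2D6 abundance per phenotype (EM mean 8 pmol/mg microsomal
protein, IM = 0.364×EM, PM = 0, UM = 2×EM; CV 60%). Populations come in a
default phenotype mix (EM 0.80 / IM 0.10 / PM 0.07 / UM 0.03) or as
uniform-phenotype cohorts, organized as trials (default 10 trials × 10
subjects).

**Clearance (IVIVE + well-stirred liver).** CYP2D6 kinetics (Vmax =
70 pmol/min/pmol enzyme, Km = 38.6 µM) scale to whole-liver unbound
intrinsic clearance via

```
CLint_u = (Vmax/Km) · abundance · MPPGL · liver mass
```

plus one lumped linear non-CYP2D6 pathway. The well-stirred model converts
total CLint to hepatic blood clearance CL_h = Q·fu_B·CLint/(Q + fu_B·CLint)
and availability F_h = Q/(Q + fu_B·CLint), with fu_B = fup/(B:P)
(fup = 0.14, B:P = 1.5). Two printed clinical anchors calibrate the unknowns:
the single-dose PM/EM AUC ratio (2.1-fold) fixes the CYP2D6 fraction
metabolized (fm ≈ 0.524), and the observed mean AUC(0–∞) after a 100 mg
single dose in young adults (1308 ng·h/mL) fixes the absolute scale. A
third anchor — clearance ≈ 50% lower in the elderly — fits one geriatric
enzyme-capacity scalar.

**Kinetics.** A minimal-PBPK structure: first-order gut depot
(ka = 2·Peff/R ≈ 2.33 h⁻¹), central volume (Vss − Vsac)·weight with
Vss = 21 L/kg, peripheral Vsac = 6 L/kg exchanging at Q = 0.5 L/h, hepatic
elimination from central. The linear system is propagated exactly with
per-subject matrix exponentials; an optional Michaelis–Menten mode verifies
that the linearization is faithful at therapeutic concentrations (≪ Km).

## Worked example

```python
from fluvopbpk import studies

model = studies.calibrate_model(seed=1)
print(f"fm (CYP2D6)     : {model.calibration.fm_closed_form:.4f}")
print(f"aging scalar    : {model.aging.clint_scalar_geriatric:.3f}")

res = studies.run_phenotype_study(model, doses=(100.0,))
print(res.folds[["phenotype", "fold_auc_vs_EM"]].to_string(index=False))
print(res.window[["phenotype", "mean_cmin"]].to_string(index=False))
```

prints

```
fm (CYP2D6)     : 0.5238
aging scalar    : 0.610
phenotype  fold_auc_vs_EM
       IM        1.454383
       PM        2.041234
       UM        0.681309
phenotype  mean_cmin
       EM  81.283583
       IM 126.434660
       PM 187.092018
       UM  51.183609
```

Reading: at 100 mg/day in geriatric uniform-phenotype populations, poor
metabolizers accumulate ~2.0-fold the EM steady-state exposure and their
mean trough sits in the upper part of the 60–230 ng/mL window, while
ultrarapid metabolizers sit at ~0.68-fold with troughs near the lower
bound — the exposure pattern behind phenotype-stratified dose bands
(roughly 50 mg/day for PMs up to 150–200 mg/day for UMs).

The same pipeline is exposed on the command line:

```bash
fluvopbpk calibrate --seed 1 --out results
fluvopbpk run --study phenotype --seed 1 --doses 50,100 --out results
fluvopbpk run --study verification --seed 1 --out results
```

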