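# Clinical PK study designs used for model verification, with the observed
# population mean/SD values reported in the corresponding publications.
# The 100 mg single-dose study (Bahrami) is the absolute-clearance
# calibration anchor; the remaining designs are hold-outs judged against
# the a-priori two-fold acceptance criterion.
verification:
  - label: bahrami_100mg_single
    reference: "Bahrami et al."
    role: calibration_anchor
    age_min: 24
    age_max: 30
    prop_female: 0.0
    geriatric: false
    dose_mg: 100.0
    interval_h: 24.0
    n_doses: 1
    duration_h: 96.0
    auc_window: 0-inf
    observed: {cmax_mean: 46.2, cmax_sd: 29.0, auc_mean: 1308.0, auc_sd: 781.0}
  - label: orlando_50mg_single_elderly
    reference: "Orlando et al."
    role: verification
    age_min: 66
    age_max: 80
    prop_female: 0.0
    geriatric: true
    dose_mg: 50.0
    interval_h: 24.0
    n_doses: 1
    duration_h: 96.0
    auc_window: 0-96
    observed: {cmax_mean: 31.0, cmax_sd: 19.0, auc_mean: 885.0, auc_sd: 560.0}
  - label: fleishaker_50mg_single
    reference: "Fleishaker et al."
    role: verification
    age_min: 20
    age_max: 44
    prop_female: 0.0
    geriatric: false
    dose_mg: 50.0
    interval_h: 24.0
    n_doses: 1
    duration_h: 96.0
    auc_window: 0-24
    observed: {cmax_mean: 21.5, cmax_sd: 4.9, auc_mean: 328.0, auc_sd: 84.6}
  - label: fleishaker_100mg_daily
    reference: "Fleishaker et al."
    role: verification
    age_min: 20
    age_max: 44
    prop_female: 0.0
    geriatric: false
    dose_mg: 100.0
    interval_h: 24.0
    n_doses: 14
    auc_window: 0-24
    observed: {cmax_mean: 99.3, cmax_sd: 35.0, auc_mean: 1762.0, auc_sd: 737.0}
  - label: spigset_50mg_bid
    reference: "Spigset et al."
    role: verification
    age_min: 23
    age_max: 34
    prop_female: 0.0
    geriatric: false
    dose_mg: 50.0
    interval_h: 12.0
    n_doses: 28
    auc_window: 0-12
    observed: {cmax_mean: 77.7, cmax_sd: 31.2, auc_mean: 761.1, auc_sd: 302.2}
  - label: spigset_100mg_bid
    reference: "Spigset et al."
    role: verification
    age_min: 23
    age_max: 34
    prop_female: 0.0
    geriatric: false
    dose_mg: 100.0
    interval_h: 12.0
    n_doses: 28
    auc_window: 0-12
    observed: {cmax_mean: 234.9, cmax_sd: 100.0, auc_mean: 2401.4, auc_sd: 1031.1}
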