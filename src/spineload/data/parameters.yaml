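# Model parameter tables and scaling constants.
#
# PCSA and segment-mass tables are transcribed cell-for-cell from published
# base-model / female-specific columns.  PCSAs are interpreted as per-side
# values (set bilateral_pcsa: true if a table is to be read as bilateral sums).

specific_tension: 90.0        # N/cm^2, applied uniformly to all fascicles
bilateral_pcsa: false

reference_subject:            # anchor for the length-mass-fat strength scaling
  sex: male
  stature: 1.75               # m
  mass: 75.0                  # kg
  age: 30.0
  fat_fraction: 0.20

# Body-fat fraction from BMI: fraction = slope * BMI + intercept, clamped to
# [0, 0.75].  The coefficients are a documented Deurenberg-style stand-in for
# the (uncited-in-print) regression; both are configurable.
fat_regression:
  female: {slope: 0.0120, intercept: 0.0200}
  male:   {slope: 0.0120, intercept: -0.0880}
  bmi_window: [15.0, 35.0]

# strength scale = (lean-mass ratio)^lean_exponent / (stature ratio)^stature_exponent
scaling:
  lean_exponent: 1.0
  stature_exponent: 1.0

pcsa_cm2:
  base:                       # shared by male and female base-models
    multifidus: 14.07
    erector_spinae: 27.89
    quadratus_lumborum: 4.41
    psoas_major: 14.63
    internal_oblique: 6.24
    external_oblique: 6.24
    rectus_abdominis: 7.80
  female_specific:
    multifidus: 9.49
    erector_spinae: 16.14
    quadratus_lumborum: 2.44
    psoas_major: 10.67
    internal_oblique: 6.30
    external_oblique: 7.08
    rectus_abdominis: 6.37

mass_fractions_pct:
  base:
    head: 8.10
    thorax: 21.60
    lumbar: 13.90
    pelvis: 14.20
    thighs: 20.00
    shanks: 9.30
    feet: 2.90
    upper_arms: 5.60
    lower_arms: 3.20
    hands: 1.20
  female_specific:
    head: 7.97
    thorax: 20.25
    lumbar: 12.43
    pelvis: 11.54
    thighs: 26.62
    shanks: 10.24
    feet: 2.60
    upper_arms: 4.70
    lower_arms: 2.60
    hands: 1.04

# Participant-group distributions used by the synthetic-subject sampler
# (mean, sd); truncation at +/- 3 sd.
population:
  female: {stature_cm: [168.5, 3.5], mass_kg: [56.4, 4.5], age_yr: [31.9, 7.6]}
  male:   {stature_cm: [176.9, 8.8], mass_kg: [77.3, 9.8], age_yr: [33.0, 7.4]}
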