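# Surface-EMG configuration: the fixed 12-electrode montage (bilateral
# multifidus, lumbar and thoracic erector spinae, external/internal oblique,
# rectus abdominis) and its mapping onto model fascicles.
#
# `carrier_amplitude_mv` is the per-site RMS of the synthetic raw signal at
# maximal contraction; `mvc_trials` is the number of generated MVC trials.

rate_hz: 2000
bandpass_hz: [30.0, 450.0]
envelope_cutoff_hz: 3.0
filter_order: 2
carrier_amplitude_mv: 1.0
mvc_trials: 3

sites:
  mf_left:  [mf_l1_l, mf_l2_l, mf_l3_l, mf_l4_l, mf_l5_l]
  mf_right: [mf_l1_r, mf_l2_r, mf_l3_r, mf_l4_r, mf_l5_r]
  les_left:  [esl_l1_l, esl_l2_l, esl_l3_l, esl_l4_l]
  les_right: [esl_l1_r, esl_l2_r, esl_l3_r, esl_l4_r]
  tes_left:  [ltpt_l, ilpt_l]
  tes_right: [ltpt_r, ilpt_r]
  eo_left:  [eo_l]
  eo_right: [eo_r]
  io_left:  [io_l]
  io_right: [io_r]
  ra_left:  [ra_l]
  ra_right: [ra_r]
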