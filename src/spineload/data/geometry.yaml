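# Trunk geometry for the simplified 7-body spine chain
# (pelvis - L5 - L4 - L3 - L2 - L1 - thorax, 6 spherical joints).
#
# Coordinate frames are right-handed: X anterior, Y to the subject's left,
# Z superior.  Anchor coordinates are metres in the owning segment's frame at
# the 1.75 m reference stature and are scaled linearly with stature.
# Segment frame origins sit at each segment's inferior (proximal) joint;
# the pelvis frame origin is the L5-S1 joint centre.
#
# Only the left-side (y > 0) fascicles are listed; right-side mirrors are
# generated automatically.  `weight` is the fascicle's share of its muscle
# group's PCSA (weights sum to 1 per group and side).

gravity: 9.81                 # m/s^2
reference_stature: 1.75       # m
sacral_tilt_deg: 0.0          # rotation of the S1 endplate frame vs pelvis

segment_fractions:            # of stature
  l5s1_height: 0.58           # floor to L5-S1 in upright standing
  lumbar_height: 0.1035       # L5-S1 to T12-L1 (split equally over 5 bodies)
  thorax_height: 0.305        # T12-L1 to the cranial end of the thorax

com_offsets:                  # metres at reference stature, segment frame
  lumbar_anterior: 0.000
  thorax: [0.020, 0.0, 0.128] # slightly anterior; ~42% up the thorax
  head:   [0.020, 0.0, 0.370] # in the thorax frame, above the thorax
  shoulder: [0.000, 0.20, 0.275]  # left shoulder joint in the thorax frame

arm_com_fractions:            # position along the shoulder-to-hand line
  upper_arm: 0.35
  lower_arm: 0.70
  hand: 1.00

iap:
  max_pressure_kpa: 26.6
  effective_area_m2: 0.010
  lever_arm_m: 0.050          # anterior offset of the abdominal resultant

stiffness_nm_per_deg:         # linear passive joint stiffness, per plane
  flexion: 0.0
  lateral: 0.0
  axial: 0.0

fascicles:
- name: mf_l1
  muscle: multifidus
  group: local
  weight: 0.128
  origin:
    segment: pelvis
    xyz: [-0.05, 0.025, -0.05]
  insertion:
    segment: L1
    xyz: [-0.047, 0.018, 0.018]
- name: mf_l2
  muscle: multifidus
  group: local
  weight: 0.128
  origin:
    segment: pelvis
    xyz: [-0.05, 0.025, -0.05]
  insertion:
    segment: L2
    xyz: [-0.047, 0.018, 0.018]
- name: mf_l3
  muscle: multifidus
  group: local
  weight: 0.128
  origin:
    segment: pelvis
    xyz: [-0.05, 0.025, -0.05]
  insertion:
    segment: L3
    xyz: [-0.047, 0.018, 0.018]
- name: mf_l4
  muscle: multifidus
  group: local
  weight: 0.128
  origin:
    segment: pelvis
    xyz: [-0.05, 0.025, -0.05]
  insertion:
    segment: L4
    xyz: [-0.047, 0.018, 0.018]
- name: mf_l5
  muscle: multifidus
  group: local
  weight: 0.128
  origin:
    segment: pelvis
    xyz: [-0.05, 0.025, -0.05]
  insertion:
    segment: L5
    xyz: [-0.047, 0.018, 0.018]
- name: rot_pelvis
  muscle: multifidus
  group: local
  weight: 0.06
  origin:
    segment: pelvis
    xyz: [-0.03, 0.038, -0.03]
  insertion:
    segment: L5
    xyz: [-0.05, 0.008, 0.014]
- name: rot_l5
  muscle: multifidus
  group: local
  weight: 0.06
  origin:
    segment: L5
    xyz: [-0.03, 0.038, 0.01]
  insertion:
    segment: L4
    xyz: [-0.05, 0.008, 0.014]
- name: rot_l4
  muscle: multifidus
  group: local
  weight: 0.06
  origin:
    segment: L4
    xyz: [-0.03, 0.038, 0.01]
  insertion:
    segment: L3
    xyz: [-0.05, 0.008, 0.014]
- name: rot_l3
  muscle: multifidus
  group: local
  weight: 0.06
  origin:
    segment: L3
    xyz: [-0.03, 0.038, 0.01]
  insertion:
    segment: L2
    xyz: [-0.05, 0.008, 0.014]
- name: rot_l2
  muscle: multifidus
  group: local
  weight: 0.06
  origin:
    segment: L2
    xyz: [-0.03, 0.038, 0.01]
  insertion:
    segment: L1
    xyz: [-0.05, 0.008, 0.014]
- name: rot_l1
  muscle: multifidus
  group: global
  weight: 0.06
  origin:
    segment: L1
    xyz: [-0.03, 0.038, 0.01]
  insertion:
    segment: thorax
    xyz: [-0.05, 0.008, 0.014]
- name: esl_l1
  muscle: erector_spinae
  group: local
  weight: 0.1
  origin:
    segment: pelvis
    xyz: [-0.045, 0.048, -0.04]
  insertion:
    segment: L1
    xyz: [-0.042, 0.04, 0.018]
- name: esl_l2
  muscle: erector_spinae
  group: local
  weight: 0.1
  origin:
    segment: pelvis
    xyz: [-0.045, 0.048, -0.04]
  insertion:
    segment: L2
    xyz: [-0.042, 0.04, 0.018]
- name: esl_l3
  muscle: erector_spinae
  group: local
  weight: 0.1
  origin:
    segment: pelvis
    xyz: [-0.045, 0.048, -0.04]
  insertion:
    segment: L3
    xyz: [-0.042, 0.04, 0.018]
- name: esl_l4
  muscle: erector_spinae
  group: local
  weight: 0.1
  origin:
    segment: pelvis
    xyz: [-0.045, 0.048, -0.04]
  insertion:
    segment: L4
    xyz: [-0.042, 0.04, 0.018]
- name: ltpt
  muscle: erector_spinae
  group: global
  weight: 0.33
  origin:
    segment: pelvis
    xyz: [-0.05, 0.03, -0.045]
  insertion:
    segment: thorax
    xyz: [-0.058, 0.03, 0.15]
  via:
  - segment: L5
    xyz: [-0.056, 0.03, 0.018]
  - segment: L4
    xyz: [-0.056, 0.03, 0.018]
  - segment: L3
    xyz: [-0.056, 0.03, 0.018]
  - segment: L2
    xyz: [-0.056, 0.03, 0.018]
  - segment: L1
    xyz: [-0.056, 0.03, 0.018]
- name: ilpt
  muscle: erector_spinae
  group: global
  weight: 0.27
  origin:
    segment: pelvis
    xyz: [-0.045, 0.065, -0.035]
  insertion:
    segment: thorax
    xyz: [-0.053, 0.07, 0.12]
  via:
  - segment: L5
    xyz: [-0.052, 0.066, 0.018]
  - segment: L4
    xyz: [-0.052, 0.066, 0.018]
  - segment: L3
    xyz: [-0.052, 0.066, 0.018]
  - segment: L2
    xyz: [-0.052, 0.066, 0.018]
  - segment: L1
    xyz: [-0.052, 0.066, 0.018]
- name: ql
  muscle: quadratus_lumborum
  group: global
  weight: 1.0
  origin:
    segment: pelvis
    xyz: [-0.02, 0.08, -0.03]
  insertion:
    segment: thorax
    xyz: [-0.01, 0.06, 0.01]
- name: pm_u
  muscle: psoas_major
  group: local
  weight: 0.5
  origin:
    segment: pelvis
    xyz: [0.025, 0.045, -0.09]
  insertion:
    segment: L2
    xyz: [0.02, 0.04, 0.018]
- name: pm_d
  muscle: psoas_major
  group: local
  weight: 0.5
  origin:
    segment: pelvis
    xyz: [0.025, 0.045, -0.09]
  insertion:
    segment: L4
    xyz: [0.02, 0.04, 0.018]
- name: ra
  muscle: rectus_abdominis
  group: global
  weight: 1.0
  origin:
    segment: pelvis
    xyz: [0.085, 0.03, -0.06]
  insertion:
    segment: thorax
    xyz: [0.09, 0.03, 0.1]
- name: eo
  muscle: external_oblique
  group: global
  weight: 1.0
  origin:
    segment: pelvis
    xyz: [0.09, 0.005, -0.02]
  insertion:
    segment: thorax
    xyz: [0.02, 0.14, 0.03]
- name: io
  muscle: internal_oblique
  group: global
  weight: 1.0
  origin:
    segment: pelvis
    xyz: [0.005, 0.145, -0.02]
  insertion:
    segment: thorax
    xyz: [0.085, 0.01, 0.035]
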