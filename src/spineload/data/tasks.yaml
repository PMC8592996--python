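# The twelve static load-handling tasks.
#
# Postures are qualitative in the study protocol; the angle values below are
# the package's documented defaults and every one can be overridden.  Angles
# in degrees; positive flexion = forward bend, positive lateral = bend to the
# left, positive axial = rotation to the left (so a right twist is negative).
#
# Hand targets are given in the world frame as fractions of stature
# (x anterior reach, y lateral, z height above the floor); named height
# classes map to z fractions via `height_classes`.  Bilateral tasks mirror
# the hand template to (y, -y); unilateral tasks load the right hand only.

height_classes: {knee: 0.30, thigh: 0.42, hip: 0.55, chest: 0.72, shoulder: 0.82, head: 0.95}

hold_duration_s: 3.0

tasks:
  T1:
    description: relaxed upright standing
    load: {kind: none, mass: 0.0}
    posture: {pelvis_tilt: 0.0, flexion: 0.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: thigh, reach: 0.02, lateral: 0.11}
  T2:
    description: full upper-body flexion, straight knees, no load
    load: {kind: none, mass: 0.0}
    posture: {pelvis_tilt: 45.0, flexion: 45.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: knee, reach: 0.18, lateral: 0.11}
  T3:
    description: two 5 kg dumbbells, arms at the sides, thigh height
    load: {kind: dumbbells, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 5.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: thigh, reach: 0.02, lateral: 0.12}
  T4:
    description: two 5 kg dumbbells, arms abducted 45 deg, hip height
    load: {kind: dumbbells, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 5.0, lateral: 0.0, axial: 0.0, arm_abduction: 45.0}
    hands: {height_class: hip, reach: 0.03, lateral: 0.20}
  T5:
    description: two 5 kg dumbbells, arms abducted 90 deg, shoulder height
    load: {kind: dumbbells, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 5.0, lateral: 0.0, axial: 0.0, arm_abduction: 90.0}
    hands: {height_class: shoulder, reach: 0.00, lateral: 0.30}
  T6:
    description: 10 kg box in front of and close to the body, hip height
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 10.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: hip, reach: 0.15, lateral: 0.10}
  T7:
    description: 10 kg box close to the body, chest height
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 5.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: chest, reach: 0.15, lateral: 0.10}
  T8:
    description: 10 kg box close to the body, head height
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 0.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: head, reach: 0.15, lateral: 0.10}
  T9:
    description: 10 kg box at chest height with extended elbows
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 10.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: chest, reach: 0.28, lateral: 0.10}
  T10:
    description: 10 kg box with flexed back and extended knees
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 30.0, flexion: 40.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: knee, reach: 0.25, lateral: 0.10}
  T11:
    description: 10 kg box held in one (right) hand
    load: {kind: box, mass: 10.0, unilateral: true}
    posture: {pelvis_tilt: 0.0, flexion: 10.0, lateral: 0.0, axial: 0.0}
    hands: {height_class: hip, reach: 0.15, lateral: 0.05}
  T12:
    description: 10 kg box in front of the body, trunk twisted to the right
    # 45 deg whole-trunk twist: facet-limited lumbar rotation (~3 deg/level)
    # carries 15 deg; the remaining 30 deg is pelvic/hip rotation.
    load: {kind: box, mass: 10.0}
    posture: {pelvis_tilt: 0.0, flexion: 10.0, lateral: 0.0, axial: -15.0, pelvis_axial: -30.0}
    hands: {height_class: hip, explicit: [[0.11, 0.04, 0.55], [0.11, -0.17, 0.55]]}

# Lumbar rhythm: fraction of the total trunk-pelvis rotation taken by each
# intervertebral joint, cranial to caudal (T12-L1, L1-L2, ..., L5-S1).
# Each plane's fractions sum to 1.
rhythm:
  flexion: [0.10, 0.12, 0.15, 0.18, 0.21, 0.24]
  lateral: [0.20, 0.18, 0.17, 0.16, 0.15, 0.14]
  axial:   [0.17, 0.17, 0.17, 0.17, 0.16, 0.16]
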