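# Healthy-model calibration targets: cumulative rotation of each vertebra
# with respect to the sacrum, in degrees, per movement.
#
# The whole-lumbar (L1) maxima are the healthy-model range-of-motion values
# the calibration must reproduce; the per-level distribution follows the
# radiological per-level pattern (see data/radiology_reference.csv) rescaled
# to the L1 maximum.  Axial rotation has no radiological arm; segmental
# rotations are distributed uniformly, consistent with the observation that
# vertebral rotations in torsion do not differ noticeably between levels.
FLX:
  L1: 34.40
  L2: 30.66
  L3: 25.12
  L4: 18.34
  L5: 9.82
EXT:
  L1: 35.58
  L2: 31.39
  L3: 29.12
  L4: 22.28
  L5: 11.63
LB:
  L1: 19.33
  L2: 16.59
  L3: 13.32
  L4: 7.81
  L5: 3.48
AR:
  L1: 9.96
  L2: 7.968
  L3: 5.976
  L4: 3.984
  L5: 1.992
# Per-segment acceptance tolerance for the calibration loop, degrees.
tolerance_deg: 0.25
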