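# Muscle geometry and movement sets for the energy-minimizing calibration.
# The psoas major is the local muscle: one slip per lumbar vertebra running
# from an anterolateral attachment on the body to a fixed pelvic/femoral
# anchor.  The remaining groups are global muscles modelled as nonnegative
# per-vertebra moment fascicles about the movement axis.
local:
  psoas_major:
    # attachment offset from the body centroid: anterior of the body surface
    attachment_anterior_offset: 8.0   # mm beyond the anterior surface
    # anchor in sacrum coordinates (x, y, z), mm: anteroinferior (lesser
    # trochanter direction, collapsed to the sagittal plane)
    anchor: [0.0, -70.0, -120.0]
    movements: [FLX]
# Global muscles list, with their action sign about each movement's axis:
# +1 drives the movement (agonist), -1 opposes it (antagonist / eccentric
# control); bilateral groups carry both signs.  All magnitudes remain
# nonnegative; antagonist fascicles let the calibration shape non-monotone
# segmental patterns, exactly the role of co-activation in vivo.
global:
  rectus_abdominis: {actions: {FLX: [1], EXT: [-1]}}
  erector_spinae:   {actions: {FLX: [-1], EXT: [1], LB: [1, -1]}}
  obliques:         {actions: {LB: [1, -1], AR: [1, -1]}}
  multifidus:       {actions: {LB: [1, -1], AR: [1, -1]}}
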