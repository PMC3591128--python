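# Parametric default geometry of the L1-sacrum column (units: mm, degrees).
# Every dimension is a named parameter; the defaults are average adult-male
# values from standard anatomy references.  Coordinate convention: x
# mediolateral (sagittal mirror plane at x=0), y anteroposterior with the
# anterior direction at -y, z cranial.  The sagittal plane is YZ, the
# frontal plane XZ, the horizontal plane XY.
levels: [L5, L4, L3, L2, L1]   # bottom-up above the sacrum

body_height:  {L1: 26.0, L2: 26.5, L3: 27.0, L4: 27.0, L5: 27.5, S: 30.0}
body_width:   {L1: 43.0, L2: 45.0, L3: 47.0, L4: 49.0, L5: 51.0, S: 52.0}
body_depth:   {L1: 31.0, L2: 32.0, L3: 33.0, L4: 34.0, L5: 35.0, S: 35.0}
disc_height:  {L1-L2: 9.0, L2-L3: 10.0, L3-L4: 11.0, L4-L5: 12.0, L5-S1: 11.0}

# Sagittal wedge angle of each joint in the neutral, lordotic posture
# (extension-direction tilt of the upper frame, degrees).
lordosis_deg: {L1-L2: 2.0, L2-L3: 3.0, L3-L4: 5.0, L4-L5: 8.0, L5-S1: 12.0}

disc:
  # Disc ellipse semi-axes as a fraction of the vertebral body half-width /
  # half-depth of the lower vertebra.
  radius_fraction: 0.95
  nucleus_area_fraction: 0.4
  # Volumetric penalty enforcing nucleus incompressibility, as a multiple of
  # the annulus Young modulus.
  nucleus_penalty_bulk_factor: 500.0
  # Interlamellar shear correction of the annulus ground substance: the
  # lamellae slide on one another, so the matrix transmits far less shear
  # (in-plane shear and torsion) than a solid section would; torsion
  # restraint is carried mainly by the crossed fibres and the facets.
  annulus_shear_correction: 0.4

fibers:
  n_layers: 5
  angle_inner_deg: 35.0    # innermost crossed sheet, from the transverse plane
  angle_outer_deg: 80.0    # outermost sheet
  volume_fraction: 0.10    # collagen fibre volume fraction of the annulus
  samples_per_family: 12

# Ligament attachment construction: the anteroposterior anchor is either the
# anterior or posterior body surface (offset added outward), "lateral" means
# an absolute y offset with x set from the body half-width.  z_span_extra is
# added above/below the disc half-height at both attachments (process span).
# Cross sections are mm^2 and are per side for bilateral ligaments.
ligaments:
  ALL: {anchor: anterior,  ap_offset: 0.0,  lateral: 0.0,  z_span_extra: 3.0, cross_section: 38.0, bilateral: false}
  PLL: {anchor: posterior, ap_offset: -2.0, lateral: 0.0,  z_span_extra: 3.0, cross_section: 20.0, bilateral: false}
  LF:  {anchor: posterior, ap_offset: 16.0, lateral: 0.0,  z_span_extra: 4.0, cross_section: 60.0, bilateral: false}
  CL:  {anchor: posterior, ap_offset: 12.0, lateral: 15.0, z_span_extra: 4.0, cross_section: 40.0, bilateral: true}
  ISL: {anchor: posterior, ap_offset: 35.0, lateral: 0.0,  z_span_extra: 5.0, cross_section: 35.0, bilateral: false}
  SSL: {anchor: posterior, ap_offset: 52.0, lateral: 0.0,  z_span_extra: 6.0, cross_section: 25.0, bilateral: false}
  ITL: {anchor: lateral,   ap_offset: 5.0,  lateral: 15.0, z_span_extra: 5.0, cross_section: 10.0, bilateral: true}
  # The iliolumbar ligament exists only at the lowest level, anchored to the
  # iliac crest (modelled as ground).
  ILL: {anchor: lateral,   ap_offset: 8.0,  lateral: 18.0, z_span_extra: 8.0, cross_section: 30.0, bilateral: true}

facets:
  lateral_offset: 15.0     # mm from the midline
  posterior_offset: 10.0   # mm behind the posterior body surface
  gap: 0.5                 # mm, neutral articular clearance
  stiffness: 200.0         # N/mm unilateral penalty
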