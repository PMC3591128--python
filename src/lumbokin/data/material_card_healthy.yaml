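# Healthy lumbar material card (MPa, dimensionless strains).
# Ligaments follow a bilinear tension-only law: modulus E1 up to the
# transition strain, E2 beyond it.  Fibre layers are tension-only linear,
# numbered from the innermost (1) to the outermost (5) annulus sheet.
name: healthy
annulus:
  E: 4.2
  nu: 0.45
nucleus:
  model: mooney_rivlin
  C01: 0.0343
  C10: 0.1369
  incompressible: true
fiber_layers:
  E: [360.0, 408.0, 455.0, 503.0, 550.0]
  nu: 0.3
cartilage:
  E: 50.0
  nu: 0.4
ligaments:
  ALL: {E1: 7.8,  transition_strain: 0.12,  E2: 20.0}
  PLL: {E1: 10.0, transition_strain: 0.11,  E2: 50.0}
  LF:  {E1: 15.0, transition_strain: 0.062, E2: 19.0}
  ITL: {E1: 10.0, transition_strain: 0.18,  E2: 59.0}
  CL:  {E1: 7.5,  transition_strain: 0.25,  E2: 33.0}
  ISL: {E1: 8.0,  transition_strain: 0.20,  E2: 15.0}
  SSL: {E1: 10.0, transition_strain: 0.14,  E2: 12.0}
  ILL: {E1: 7.8,  transition_strain: 0.12,  E2: 20.0}
# Vertebral bone zones, metadata only: vertebrae are rigid in the reduced
# model (bone is 2-4 orders of magnitude stiffer than discs and ligaments).
bone:
  outer_endplate:        {E: 12000.0, nu: 0.3}
  intermediate_endplate: {E: 6000.0,  nu: 0.3}
  centre_endplate:       {E: 2000.0,  nu: 0.3}
  body_walls:            {E: 12000.0, nu: 0.3}
  cancellous:            {E: 100.0,   nu: 0.2}
  posterior_elements:    {E: 3000.0,  nu: 0.3}
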