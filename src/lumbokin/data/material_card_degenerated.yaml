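# Degenerated-disc material card.  Only the disc constituents change with
# degeneration: stiffer, less Poisson-confined annulus matrix, a compressible
# elastic nucleus (dehydration), and fibre moduli reduced tenfold.  Every
# field not listed here is inherited from the healthy card on load.
name: degenerated
annulus:
  E: 6.0
  nu: 0.35
nucleus:
  model: elastic
  E: 1.3
  nu: 0.4
fiber_layers:
  E: [36.0, 40.8, 45.5, 50.3, 55.0]
  nu: 0.3
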