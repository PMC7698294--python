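# Default design space for the scaled sweep: fiber morphology and
# deposition parameters explored by latin-hypercube sampling.
params:
  aspect_ratio:
    kind: continuous
    range: [25.0, 55.0]
  wall_thickness_um:
    kind: continuous
    range: [0.10, 0.25]
  flexibility:
    kind: levels
    levels: [0, 1]
  target_layers:
    kind: continuous
    range: [4.0, 9.0]
  mixture_weight:
    kind: continuous
    range: [0.0, 0.5]
scheme: latin-hypercube
n_designs: 200
seeds_per_design: 5
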