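# Committed calibration for the reference surface-porosity reproduction.
# Population widths span the measured 0.0685-9.8 um range (log-uniform);
# layer count and top-view visibility depth were fitted once against the
# reference computational porosity and are fixed here.
domain_px: [192, 192]
resolution_um_per_voxel: 0.5
target_layers: 9.5
population:
  width_range_um: [0.0685, 9.8]
  width_law: log-uniform
  aspect_ratio: 15.0
  wall_thickness_um: 0.3
  lumen_um: 0.0
  flexibility: 0
  mixture_weight: 0.5
seed: 0
boundary: periodic
top_view_depth_voxels: 12
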