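# Base simulation config for the design-space sweep: 28.8 um square field
# at 0.3 um/voxel with a 6-voxel top-view visibility depth.  Width range
# spans the measured fiber-width interval; individual designs override the
# population parameters listed in default_space.yaml.
domain_px: [96, 96]
resolution_um_per_voxel: 0.3
target_layers: 6.0
population:
  width_range_um: [0.0685, 9.8]
  width_law: two-mode
  aspect_ratio: 40.0
  wall_thickness_um: 0.15
  lumen_um: 0.0
  flexibility: 1
  mixture_weight: 0.3
seed: 0
boundary: periodic
top_view_depth_voxels: 6
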