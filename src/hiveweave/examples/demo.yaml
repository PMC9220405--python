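# Default demo hive: a 30 L nest (the middle of the 25-40 L feral
# colony preference band) with the full feature set: weave and channel
# zones, thick woven roof, entrance bore and landing platform.
pipeline: vo
seed: 0
out_dir: out/demo
spec:
  cavity_target_volume: 30.0     # L, inside the 25-40 L preference band
  cavity_height: 50.0            # cm
  entrance_diameter: 60.0        # mm
  channel_diameter: 18.0         # mm
  roof_thickness: 60.0           # mm
  landing_platform: [100.0, 80.0]
  design_load: 80.0
  occupancy: 60000
schedule:
  - {distance: 3.0, role: wall}
  - {distance: 20.0, role: weave}
  - {distance: 18.0, role: channel}
  - {distance: 3.0, role: wall}
machine:
  max_print_diameter: 70.0       # cm
  max_module_height: 15.0        # cm
  bead_width: 3.0
  layer_height: 2.0
  filament_diameter: 2.85
vo:
  cell_size: 8.0
validation:
  cavity_volume_l: [25.0, 40.0]
  entrance_diameter_mm: [40.0, 80.0]
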