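# GrowLay Hive-2: filament-printed scaffold with a 45 L inner nest volume.
# Only the nest volume is documented for the built hive; heights, wall
# schedule, cell size and the machine bed are reconstructions chosen to give
# realistic standing-hive proportions on a large-format FDM printer.
pipeline: vo
seed: 0
out_dir: out/growlay_hive2
note: reconstruction; 45 L nest volume is the documented quantity
spec:
  cavity_target_volume: 45.0     # L
  cavity_height: 60.0            # cm
  entrance_diameter: 60.0        # mm, reconstruction (no documented value)
  channel_diameter: 18.0         # mm, vertical inoculation tubes
  roof_thickness: 60.0           # mm of fully woven roof
  landing_platform: [120.0, 80.0]
  design_load: 80.0              # kgf, full colony + stores
  occupancy: 60000
schedule:
  - {distance: 3.0, role: wall}
  - {distance: 20.0, role: weave}
  - {distance: 18.0, role: channel}
  - {distance: 3.0, role: wall}
machine:
  max_print_diameter: 70.0       # cm, large-format FDM
  max_module_height: 15.0        # cm
  bead_width: 3.0                # mm
  layer_height: 2.0              # mm
  filament_diameter: 2.85        # mm
vo:
  cell_size: 8.0                 # mm ("infill-feed" resolution)
fabrication:
  shrinkage: 0.0                 # thermoplastic: no drying shrinkage
  material_density: 1.1
validation:
  cavity_volume_l: [25.0, 50.0]  # Hive-2 deliberately exceeds the 25-40 L feral band
  entrance_diameter_mm: [40.0, 80.0]
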