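# Mycelial clay hive at as-printed scale: 39 L nest volume before the
# ~20% drying/firing shrinkage took it to about 30 L. The 40 cm bed and
# 15 cm module height limit are the documented fabrication constraints;
# wall thicknesses ("the walls of the mid-body parts had to be thinner")
# and heights are reconstructions. The landing platform is an attach-on
# part: it does not fit the 40 cm bed together with the body.
pipeline: vo
seed: 0
out_dir: out/clay_hive
note: reconstruction; 39 L as-printed nest volume and machine limits documented
spec:
  cavity_target_volume: 39.0     # L, as-printed (pre-shrinkage)
  cavity_height: 52.0            # cm
  entrance_diameter: 60.0        # mm, reconstruction
  channel_diameter: 15.0         # mm
  roof_thickness: 50.0           # mm
  landing_platform: null
  design_load: 80.0
  occupancy: 60000
schedule:
  - {distance: 2.0, role: wall}
  - {distance: 15.0, role: weave}
  - {distance: 18.0, role: channel}
  - {distance: 2.0, role: wall}
machine:
  max_print_diameter: 40.0       # cm, documented limit
  max_module_height: 15.0        # cm, documented limit (layer collapse)
  bead_width: 3.0                # mm, paste bead
  layer_height: 2.0              # mm
  filament_diameter: null        # paste extruder
vo:
  cell_size: 7.0
fabrication:
  shrinkage: 0.2                 # linear, "nearly 20%" drying+firing
  material_density: 1.9
validation:
  cavity_volume_l: [25.0, 40.0]
  entrance_diameter_mm: [40.0, 80.0]
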