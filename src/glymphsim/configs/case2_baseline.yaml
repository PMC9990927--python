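test_case: 2
mesh_kind: synthetic
mesh_shape: sphere
mesh_volume: 2313.0
mesh_resolution: 16
mesh_path: null
mesh_format: auto
injection_centre: null
injection_sigma: 1.0
injection_amount: 1.0
sas_model: decay
alpha: null
variant: baseline
variations: []
parameter_overrides: {}
dt_min: 1.0
t_end_min: 360.0
cube_sides:
- 2.0
- 4.0
- 5.0
snapshot_times_min: []
write_fields: false
pressure_method: auto
seed: 0
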