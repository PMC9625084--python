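# Desk-scale pipeline configuration: trains both networks from scratch in
# roughly a quarter hour on one CPU, then runs detect -> track -> events on
# a synthetic feeding movie.  Full-scale training values are the
# PipelineConfig defaults; see docs/methods.md.
optics:
  center_wavelength_nm: 632.0
  filter_bandwidth_nm: 18.0
  sensor_size_mm: [4.608, 3.686]
  sensor_pixels: [1280, 1024]
  medium_refractive_index: 1.33
  dn_dc_ml_g: 0.21
  frame_interval_s: 0.1
scene:
  image_shape: [64, 64]
  n_particles: [1, 3]
  z_range_um: [500.0, 1500.0]
sequence:
  z_range_um: [500.0, 1500.0]
runet:
  down_filters: [8, 16, 32, 48]
  up_filters: [48, 32, 16, 8]
  seg_up_filters: [16, 12, 8, 6]
  convs_per_block: 2
  input_shape: [64, 64]
runet_train:
  learning_rate: 0.003
  lr_schedule: cosine
  batch_size: 4
  epochs: 32
  n_samples: 500
  prebuffer: 250
  loss_weights: {z: 3.0, mass: 3.0}
  seed: 7
map_codec:
  mass_encoding: log
wacnet:
  conv_filters: [8, 16, 32, 48]
  latent_dense: [64, 64]
  weight_head: [64, 1]
  output_head: [32, 32, 2]
wacnet_train:
  learning_rate: 0.001
  lr_schedule: cosine
  batch_size: 8
  epochs: 16
  n_samples: 500
  prebuffer: 250
  seed: 11
wac_codec:
  optical_volume_encoding: log
decoder:
  decoder: blob
seed: 0
mass_window: 1
output_dir: holomass_out
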