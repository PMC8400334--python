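# Shipped stage-1 operating point for 112-band (1/2-binned) Per-Norm cubes.
# Band numbers are 1-based indices into the binned wavelength grid; the
# intervals are closed and in Per-Norm difference units.
visible_pair: [26, 63]
nir_pair: [68, 93]
visible_intervals:
  seaweed: [60, 80]
  belt: [20, 45]
nir_intervals:
  seaweed: [-30, -5]
  belt: [5, 25]
visible_range_nm: [400, 750]
nir_range_nm: [750, 1000]
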