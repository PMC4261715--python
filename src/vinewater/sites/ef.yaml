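# Steep-slope site "EF": shallow stony soil, wide rows, near-full cover crop.
name: EF
latitude_deg: 49.967
longitude_deg: 7.917
elevation_m: 120
slope_deg: 35
aspect_deg: 8          # west of south positive
row_azimuth_deg: 8     # rows run up and down the slope
canopy:
  row_distance_m: 2.50
  height_m: 1.00
  width_m: 0.40
  stem_height_m: 0.60
  porosity_min: 0.40
phenology:
  tt_budburst: 120
  tt_hedging: 600
  tt_abscission_start: 1600
  tt_abscission_end: 1900
  base_temperature_c: 10
soil:
  ttsw_mm: 85
  ttsw_1m_mm: 53.1     # upper 1 m share of the 1.6 m profile
  tew_mm: 26.9
  rew_mm: 11.0
  f_cc: 0.84
  p_ftsw: 0.4
  p_ftsw_cc: 0.4
  k_c_v: 0.56
measured:
  k_c_v_ratio: 0.57    # sap-flow derived site ratio
optics:
  leaf_reflectivity: 0.20
  leaf_transmittance: 0.10
  soil_albedo: 0.18
ground_albedo: 0.20
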