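# Steep-slope site "BU": narrow rows, alternating tilled inter-rows.
name: BU
latitude_deg: 49.967
longitude_deg: 7.917
elevation_m: 110
slope_deg: 27
aspect_deg: 4
row_azimuth_deg: 4
canopy:
  row_distance_m: 1.60
  height_m: 1.10
  width_m: 0.40
  stem_height_m: 0.60
  porosity_min: 0.25
phenology:
  tt_budburst: 120
  tt_hedging: 600
  tt_abscission_start: 1600
  tt_abscission_end: 1900
  base_temperature_c: 10
soil:
  ttsw_mm: 115
  ttsw_1m_mm: 71.9
  tew_mm: 21.5
  rew_mm: 9.2
  f_cc: 0.40
  p_ftsw: 0.4
  p_ftsw_cc: 0.4
  k_c_v: 0.56
measured:
  k_c_v_ratio: 0.68
optics:
  leaf_reflectivity: 0.20
  leaf_transmittance: 0.10
  soil_albedo: 0.18
ground_albedo: 0.20
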