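# Moderate-slope site "WI": deep loam, high water holding capacity.
name: WI
latitude_deg: 49.967
longitude_deg: 7.917
elevation_m: 105
slope_deg: 15
aspect_deg: -21        # east of south negative
row_azimuth_deg: -21
canopy:
  row_distance_m: 1.60
  height_m: 1.35
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
  ttsw_mm: 160
  ttsw_1m_mm: 100.0
  tew_mm: 21.4
  rew_mm: 9.1
  f_cc: 0.75
  p_ftsw: 0.4
  p_ftsw_cc: 0.4
  k_c_v: 0.56
measured:
  k_c_v_ratio: 0.42
optics:
  leaf_reflectivity: 0.20
  leaf_transmittance: 0.10
  soil_albedo: 0.18
ground_albedo: 0.20
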