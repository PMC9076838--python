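{
 "seed": 7,
 "stages": ["scene", "lifetime", "aggregates", "fcs", "denat", "turnover"],
 "acquisition": {"rep_period_ns": 50.0, "bin_width_ns": 0.25, "irf_center_ns": 2.0, "irf_fwhm_ns": 0.2},
 "scene": {
  "image_size": [96, 96],
  "n_cells": 4,
  "pixel_size_um": 0.1,
  "puncta_per_cell": 2,
  "puncta_tau_range_ns": [6.0, 7.0],
  "puncta_radius_range_px": [3.0, 4.0],
  "photons_per_pixel": 500.0
 },
 "lifetime": {"min_photons": 100},
 "aggregates": {"lifetime_threshold_ns": 5.0, "min_particle_area_px2": 4, "connectivity": 8},
 "fcs": {"rh_nm": [48.0], "fractions": [1.0], "n_mean": 5.0, "noise_sd_rel": 0.01},
 "denat": {"dg_water_kcal_mol": 2.0, "m_value": 1.0, "noise_sd": 0.01},
 "turnover": {"doubling_time_h": 20.0, "half_life_h": 41.0, "noise_sd_rel": 0.02}
}
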