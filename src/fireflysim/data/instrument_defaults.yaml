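# Shipped instrument defaults (version 0.1.0).
# Every coefficient is named exactly as in the corresponding type
# definition; unknown keys are rejected at load time.
instrument:
  band_grid:
    n_bands: 2160
    n_pixels: 266
    slope: 5.12e-2        # nm per band
    intercept: 670.12     # nm
  fwhm:
    c_d2: 2.0e-6
    c_d: -7.0e-4
    c_w: -7.0e-4
    c_0: 0.76405
    clip_lo: 0.12         # nm
    clip_hi: 0.2          # nm
    residual_sd: 7.32e-3  # nm
    form: quadratic       # quadratic | literal
  response:
    slope: -185.67        # DN per (W m-2 sr-1 nm-1) per nm
    intercept: 173943.0   # DN per (W m-2 sr-1 nm-1)
    uncertainty_slope: 2.0e-4
    uncertainty_intercept: -0.1005
    linearity_tolerance: 0.003
    dn_max: 65535
  noise:
    exponent: 0.5295
    units_mode: physical-anchored   # physical-anchored | printed
  dark:
    center_dn: 100.0
    edge_dn: 105.0
    corner_dn: 115.0
    sd_dn: 2.0
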