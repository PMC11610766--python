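{
  "grey_matter": {
    "f_water": 0.73,
    "f_fat": 0.10,
    "c_hbt_uM": 76.0,
    "sat_o2": 0.85,
    "c_oxcco_uM": 6.4,
    "c_redcco_uM": 1.6,
    "c_oxcytb_uM": 2.37,
    "c_redcytb_uM": 0.89,
    "c_oxcytc_uM": 1.36,
    "c_redcytc_uM": 0.68
  },
  "artery": {
    "f_water": 0.55,
    "f_fat": 0.01,
    "c_hbt_uM": 2324.0,
    "sat_o2": 0.98,
    "c_oxcco_uM": 0.0,
    "c_redcco_uM": 0.0,
    "c_oxcytb_uM": 0.0,
    "c_redcytb_uM": 0.0,
    "c_oxcytc_uM": 0.0,
    "c_redcytc_uM": 0.0
  },
  "vein": {
    "f_water": 0.55,
    "f_fat": 0.01,
    "c_hbt_uM": 2324.0,
    "sat_o2": 0.60,
    "c_oxcco_uM": 0.0,
    "c_redcco_uM": 0.0,
    "c_oxcytb_uM": 0.0,
    "c_redcytb_uM": 0.0,
    "c_oxcytc_uM": 0.0,
    "c_redcytc_uM": 0.0
  }
}
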