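{
  "extinction": {
    "HbO2": {
      "file": "ext_hbo2_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "Hb": {
      "file": "ext_hb_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "oxCCO": {
      "file": "ext_oxcco_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "redCCO": {
      "file": "ext_redcco_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "oxCytb": {
      "file": "ext_oxcytb_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "redCytb": {
      "file": "ext_redcytb_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "oxCytc": {
      "file": "ext_oxcytc_synthetic.csv",
      "units": "M^-1 cm^-1"
    },
    "redCytc": {
      "file": "ext_redcytc_synthetic.csv",
      "units": "M^-1 cm^-1"
    }
  },
  "background": {
    "water": {
      "file": "mua_water_synthetic.csv",
      "units": "cm^-1"
    },
    "fat": {
      "file": "mua_fat_synthetic.csv",
      "units": "cm^-1"
    }
  }
}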