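{
  "registry_version": 1,
  "note": "Extant-scaling allometries on log10-log10 axes: log10(mass[output_unit]) = slope * log10(measurement[mm]) + intercept. 'ppe' is the published percent prediction error, applied as a symmetric relative error band.",
  "equations": {
    "bipedal_femoral": {
      "slope": 2.749,
      "intercept": -0.683,
      "input": "femur_circumference",
      "output_unit": "g",
      "ppe": 0.256,
      "description": "Minimum femoral shaft circumference to body mass for bipedal non-avian vertebrates (Campione et al. 2014 correction of the quadrupedal stylopodial relation)."
    },
    "quadrupedal_stylopodial": {
      "slope": 2.754,
      "intercept": -1.097,
      "input": "combined_stylopodial_circumference",
      "output_unit": "g",
      "ppe": 0.256,
      "description": "Combined humeral plus femoral minimum shaft circumference to body mass across extant terrestrial quadrupeds (Campione & Evans 2012)."
    }
  }
}
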