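{
  "radiopharmaceuticals": [
    {
      "name": "32P-Na3PO4",
      "radionuclide": "32P",
      "physical_half_life_d": 14.268,
      "effective_half_life_d": 13.0,
      "bone_uptake_percent": 20.0,
      "administered_activity_MBq": 450.0
    },
    {
      "name": "89Sr-dichloride",
      "radionuclide": "89Sr",
      "physical_half_life_d": 50.563,
      "effective_half_life_d": 29.0,
      "bone_uptake_percent": 65.0,
      "administered_activity_MBq": 150.0
    },
    {
      "name": "153Sm-EDTMP",
      "radionuclide": "153Sm",
      "physical_half_life_d": 1.9379,
      "effective_half_life_d": 1.6,
      "bone_uptake_percent": 70.0,
      "administered_activity_MBq_per_kg": 37.0
    },
    {
      "name": "166Ho-DOTMP",
      "radionuclide": "166Ho",
      "physical_half_life_d": 1.1177,
      "effective_half_life_d": 0.93,
      "bone_uptake_percent": 30.0,
      "administered_activity_MBq": 1100.0
    },
    {
      "name": "177Lu-EDTMP",
      "radionuclide": "177Lu",
      "physical_half_life_d": 6.647,
      "effective_half_life_d": 3.9,
      "bone_uptake_percent": 60.0,
      "administered_activity_MBq_per_kg": 37.0
    },
    {
      "name": "186Re-HEDP",
      "radionuclide": "186Re",
      "physical_half_life_d": 3.7183,
      "effective_half_life_d": 2.7,
      "bone_uptake_percent": 30.0,
      "administered_activity_MBq": 5020.0
    },
    {
      "name": "188Re-HEDP",
      "radionuclide": "188Re",
      "physical_half_life_d": 0.785,
      "effective_half_life_d": 0.66,
      "bone_uptake_percent": 30.0,
      "administered_activity_MBq": 3300.0
    }
  ]
}
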