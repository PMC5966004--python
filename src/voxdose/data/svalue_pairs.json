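{
  "voxel_size_mm": 4.67,
  "units": "Gy/(MBq h)",
  "description": "Published self-irradiation and first-nearest-neighbour (face-adjacent) voxel S-values for seven bone-seeking therapy radionuclides at 4.67 mm isotropic voxel pitch, soft-tissue medium.",
  "svalues": {
    "32P": {"self": 2.1437, "neighbour": 0.218209},
    "89Sr": {"self": 1.9573, "neighbour": 0.1720},
    "153Sm": {"self": 1.3444, "neighbour": 0.03031},
    "166Ho": {"self": 2.1929, "neighbour": 0.2092},
    "177Lu": {"self": 0.7782, "neighbour": 0.01066},
    "186Re": {"self": 1.4561, "neighbour": 0.0655},
    "188Re": {"self": 2.2032, "neighbour": 0.2477}
  }
}
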