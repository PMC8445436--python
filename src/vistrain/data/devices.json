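[
  {"name": "efa", "viewing_distance_mm": 400, "angular_scale": 1.0, "fov_deg": 90},
  {"name": "svft", "viewing_distance_mm": 44, "angular_scale": 1.54, "fov_deg": 90}
]
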