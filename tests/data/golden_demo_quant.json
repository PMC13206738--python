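{
  "eye_id": "demo_40kDa_24h",
  "threshold": 70,
  "area_percent": 9.501944701618614,
  "radius_feret": 3.9258756984907204,
  "radius_centroid": 4.3731979178665314,
  "nasal_fraction": 3.433001107419712,
  "temporal_fraction": 96.56699889258029,
  "excluded_signal_fraction": 0.27609055770292656,
  "dye_label": "40 kDa",
  "time_h": 24.0,
  "injection_side": "temporal",
  "model": "synthetic demo"
}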