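{
 "af_max_pm2": 0.0001,
 "category_bands": {
  "B": [
   null,
   -7
  ],
  "LB": [
   -6,
   -1
  ],
  "LP": [
   6,
   9
  ],
  "P": [
   10,
   null
  ],
  "VUS": [
   0,
   5
  ]
 },
 "dominant_share_percent": 90.0,
 "predictive_codes": [
  "PVS1",
  "PP3",
  "BP4",
  "PP3/BP4"
 ],
 "provean_deleterious_max": -2.5,
 "ptc_escape_critical_upgrade": true,
 "revel_supportive_min": 0.7,
 "strength_floor_share_percent": 10.0
}
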