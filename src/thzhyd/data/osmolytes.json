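{
  "urea": {"molar_mass": 60.06, "kind": "denaturant"},
  "pg": {"molar_mass": 76.09, "kind": "polyol", "full_name": "propylene glycol"},
  "propylene glycol": {"molar_mass": 76.09, "kind": "polyol"},
  "deg": {"molar_mass": 106.12, "kind": "polyol", "full_name": "diethylene glycol"},
  "diethylene glycol": {"molar_mass": 106.12, "kind": "polyol"},
  "glycerol": {"molar_mass": 92.09, "kind": "polyol"},
  "fructose": {"molar_mass": 180.16, "kind": "sugar"},
  "sucrose": {"molar_mass": 342.30, "kind": "sugar"},
  "trehalose": {"molar_mass": 342.30, "kind": "sugar"}
}
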