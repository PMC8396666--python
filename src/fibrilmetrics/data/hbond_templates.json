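{
  "hydrogen_of": {
    "N": ["H", "HN", "H1", "H2", "H3"],
    "OD1": ["HD1"],
    "OG": ["HG"],
    "OG1": ["HG1"],
    "OH": ["HH", "HO"],
    "OW": ["HW1", "HW2", "H1", "H2"],
    "NE2": ["HE21", "HE22"],
    "ND2": ["HD21", "HD22"],
    "NZ": ["HZ1", "HZ2", "HZ3"]
  },
  "extra_acceptors": {
    "default": [],
    "HIS": ["ND1", "NE2"]
  },
  "water_resnames": ["SOL", "HOH", "WAT", "TIP3", "SPC"],
  "hydrogen_search_radius_nm": 0.12
}
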