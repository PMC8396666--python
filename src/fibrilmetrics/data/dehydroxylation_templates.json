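{
  "HYP": {"rename_to": "PRO", "delete_atoms": ["OD1", "HD1"], "rename_atoms": {}},
  "LYZ": {"rename_to": "LYS", "delete_atoms": ["OD1", "HD1"], "rename_atoms": {}},
  "HYL": {"rename_to": "LYS", "delete_atoms": ["OH", "HO"], "rename_atoms": {"HD1": "HD1"}}
}
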