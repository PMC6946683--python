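{
  "title": "glycomesh network document",
  "const": {"schema": "glycomesh.network/1"},
  "required": {
    "schema": "string",
    "extent": "array",
    "anchors": "array",
    "per_tip_counts": "array",
    "filaments": "array",
    "contacts": "array",
    "termini_points": "array",
    "termini_diameters": "array"
  }
}
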