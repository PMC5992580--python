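{
  "gene": "PALB2",
  "total_probands": 329,
  "published_carriers": 5,
  "exclusions": ["c.9976A>T"],
  "panels": [
    {"name": "1000G_EUR", "carriers": 1, "size": 503},
    {"name": "ExAC_nonTCGA_NFE", "carriers": 26, "size": 27173}
  ]
}
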