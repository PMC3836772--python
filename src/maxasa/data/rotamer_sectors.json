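{
  "comment": "Side-chain rotamer sector centres. Each chi angle is discretized into three 120-degree sectors named by the canonical gauche+/gauche-/trans values; the numbers below are the sector-mean chi values used when enumerating rotamer conformations. Idealized sector centres are used for every amino acid; per-amino-acid, per-chi overrides may be added as entries under 'per_aa'.",
  "default_sector_means": [60.0, -60.0, 180.0],
  "per_aa": {}
}
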