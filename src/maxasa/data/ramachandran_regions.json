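{
  "comment": "Approximate Ramachandran CORE/ALLOWED regions as unions of [phi_min, phi_max, psi_min, psi_max] rectangles (degrees), following the standard region conventions used for structure validation. These idealized masks stand in for empirically derived per-amino-acid regions when no structure corpus is available; the survey module derives exact regions from observed dihedral counts instead. Glycine uses the generic mask plus its point reflection (phi, psi) -> (-phi, -psi).",
  "generic": {
    "core": [
      [-160, -60, 100, 180],
      [-160, -60, -180, -160],
      [-140, -45, -65, 0]
    ],
    "allowed": [
      [-180, -40, 60, 180],
      [-180, -40, -180, -140],
      [-160, -40, -80, 60],
      [40, 80, 0, 80]
    ]
  },
  "proline": {
    "core": [
      [-90, -50, -50, -10],
      [-90, -50, 120, 180]
    ],
    "allowed": [
      [-110, -40, -70, 70],
      [-110, -40, 110, 180],
      [-110, -40, -180, -160]
    ]
  }
}
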