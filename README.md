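# maxasa

Maximum-allowed solvent accessibilities of residues in proteins.

## The problem

Relative solvent accessibility,

```
RSA = ASA / MaxASA(aa),
```

normalizes a residue's accessible surface area (ASA, in Å², by the
Lee–Richards rolling-probe definition with a 1.4 Å water probe) by a
per-amino-acid reference maximum, so that 0 means fully buried and 1 means
fully exposed. The historically used reference scales (Miller et al. 1987,
extended-conformation Gly-X-Gly tripeptides; Rose et al. 1985,
average-conformation tripeptides) are not tight upper bounds: real crystal
structures routinely contain residues with RSA > 1 (up to ~1.2), because
the most exposed backbone conformations are helical, not extended.

`maxasa` is for structural bioinformaticians who need well-founded
normalization constants and reproducible RSA machinery. It derives tight
maximum-ASA scales by two complementary routes:

* **theoretical** — build Gly-X-Gly tripeptides atom by atom from internal
  coordinates (NeRF construction, standard Engh–Huber-style backbone
  geometry, CCD-derived side-chain templates), exhaustively scan the
  central residue's (φ, ψ) torus crossed with three-sector χ rotamers,
  discard steric clashes, and record the maximum central-residue ASA
  (Shrake–Rupley sampling, DSSP-compatible radii);
* **empirical** — mine a corpus of PDB structures with strict quality
  filters (chain terminators, missing atoms, ambiguous occupancy, each
  with neighbours), bin observations into Ramachandran regions
  (CORE ⊆ ALLOWED ⊆ GENEROUS ⊆ ALL), and record per-bin maxima.

It also ships the published normalization tables and derives burial-based
hydrophobicity scales (1 − mean RSA, fraction 100%/95% buried) with
Pearson correlations against packaged experimental scales.

## Worked example

```python
from maxasa import scan, normtables, survey

# theoretical maximum ASA of alanine: full 5-degree phi/psi scan of
# Gly-Ala-Gly, trans peptide bonds, clashes discarded
grid = scan.scan_amino_acid("A", step=5.0, rng_seed=1)
print(round(grid.global_max(), 1))        # 128.9  (Å²)
print(normtables.get_scale("theoretical")["A"])   # 129.0

# where the maximum lives: a compact helical conformation,
# far above the extended conformation
print(grid.global_argmax()["bin"])        # (70.0, -70.0)
print(round(grid.cells[(-180.0, -180.0)]["asa"], 1))   # 112.4

# the old scales under-normalize: an alanine with ASA = 135.6 Å²
print(round(survey.rsa(135.6, "A", normtables.get_scale("miller1987")), 2))
# 1.2  -> RSA above one under the Miller scale

# percent corrections of the proposed scale vs the Rose scale
corr = normtables.correction_vs(normtables.get_scale("theoretical"),
                                normtables.get_scale("rose1985"))
print(corr["L"], corr["D"])               # 4 18   (smallest, largest)
```

The scan says the most exposed alanine conformation has ASA ≈ 129 Å² and
is helical ((φ, ψ) near (70°, −70°); the mirror right-handed helical lobe
is within 1 Å² of it), while the extended conformation manages only
≈ 112 Å² — which is why extended-conformation normalization constants are
too small.

A command-line interface mirrors the library:

```sh
maxasa scan --aa A --step 5 --seed 1 --out grid.tsv
maxasa scan --all --step 20 --seed 1          # per-region summary table
maxasa normalize my_asa.tsv --scale rose1985
maxasa survey pdb_dir/ --out observations.tsv
maxasa hydro --corpus pdb_dir/ --scale theoretical-allowed
```

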