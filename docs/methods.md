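# Methods

## Tripeptide model

The reference object is the Gly-X-Gly tripeptide: the residue of interest
X flanked by glycines, the flanking choice that occludes the least solvent
and therefore yields the largest attainable ASA for X. Chains are built
heavy-atom by heavy-atom with the natural-extension reference frame
(NeRF): each atom is placed at a bond length, bond angle and dihedral
relative to three previously placed atoms. Dihedrals follow the IUPAC 1970
sign convention and are stored in [−180°, 180°).

Backbone geometry uses standard restraint-style parameters, exposed as
data (`geometry.BACKBONE_PARAMS`): N–CA 1.458 Å, CA–C 1.525 Å, C–O
1.231 Å, C–N 1.329 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°,
CA-C-O 120.8°. Side-chain topology and internal coordinates are derived
once per residue type from the Chemical Component Dictionary's ideal
coordinates (via biotite's bundled CCD): the χ-defining torsions become
free parameters, branch atoms keep fixed offsets relative to their χ, and
ring torsions are frozen at their ideal values. The CB improper torsion is
taken from the ideal geometry, which fixes L-chirality (N-CA-C-CB ≈
−120°). Proline is a rigid endocyclic template with no free χ; because
the ring is built off the N–CA edge, it stays closed under any φ. φ can
optionally be restricted to [−110°, −40°] for proline scans.

The peptide bond is planar trans (ω = 180°) by default and configurable.
Flanking glycines are held extended (only their amide/carbonyl
orientations can influence the central residue). Hydrogens are never
modelled (heavy-atom convention, as in DSSP). Terminal groups are bare
(no OXT, no charges): the reference quantity is the exposure of an
*internal* residue, and chain termini are excluded from the empirical
survey for the same reason.

Setting a named dihedral is a rigid rotation of the distal side about the
bond axis; the moving set is found by graph traversal that avoids the
pivot atom, so rings through the pivot rotate as a unit. Round-trip
accuracy (build → measure) is ≤ 1e-4°, and rotations preserve all bonded
distances to 1e-9 Å (both under test).

## Accessible surface area

ASA follows the Lee–Richards definition: the area accessible to the
centre of a 1.4 Å probe rolled over the van der Waals surface. It is
computed by Shrake–Rupley point sampling with a deterministic
golden-spiral (Fibonacci) lattice, 960 points per atom by default. A
residue's ASA is the sum over its atoms, with every atom of the structure
occluding.

Radii default to the DSSP convention (`sasa.DSSP_RADII`): backbone N
1.65 Å, O 1.40 Å, carbonyl C 1.76 Å, CA 1.87 Å, and a flat 1.80 Å for
every side-chain atom. This flat side-chain radius is essential for
matching DSSP-calibrated reference values — with element-class radii a
serine OG would get 1.40 Å and the serine maximum falls ~5 Å² short. A
pure element-class table (`sasa.ELEMENT_RADIUS_TABLE`: N 1.65, O 1.40,
carbonyl C 1.76, other C 1.87, S 1.85) is available for non-DSSP work.

Numerical properties (all under test): isolated spheres match
4π(r+probe)² to <0.5%; overlapping pairs match the analytic spherical-cap
formula to <0.5%; results are exactly translation-invariant but only
rotation-invariant to quadrature tolerance (~0.3 Å² observed, bounded at
0.75 Å² in tests), since the point lattice does not co-rotate with the
molecule — a property shared by every fixed-quadrature SASA code.
Residue-level quadrature convergence |ASA(4000 pts) − ASA(960 pts)| is
≈0.5 Å² for Gly/Ala tripeptides and ≈1.1 Å² for serine (bounded at
1.25 Å² in tests). These errors are far below the ±3 Å² tolerance used
for comparisons with reference constants.

## Conformational scan

For each amino acid the central (φ, ψ) is stepped over the full torus
(default 5°, which changes the maxima by <1 Å² relative to finer grids —
the maximum varies slowly with backbone angles; grid-refinement 5° vs 2°
agrees within 1.5 Å² under test). Each χ is discretized into the three
canonical 120° sectors (gauche+, gauche−, trans) represented by
sector-mean values, packaged as data; the defaults are the idealized
sector centres (60°, −60°, 180°) since a rotamer-library snapshot to
average over is not bundled. Amino acids with more than ten sector
combinations (3, 4 χ) are subsampled: ten combinations drawn without
replacement, with a fresh seeded draw at every grid point (seed derived
from the master seed and the grid indices, so scans are exactly
reproducible). Argmax ties break lexicographically by (φ, ψ, rotamer).

Steric feasibility: a conformation is discarded when any atom pair
separated by at least four bonds comes closer than 0.85 × the sum of the
two van der Waals radii. The 0.85 factor reproduces the canonical
hard-sphere contact limits (e.g. C···C 3.18 Å against the published
3.0–3.2 Å window, C···O 2.78 vs 2.8 Å) and with it the scan's allowed-map
topology matches the classic Ramachandran picture; much looser factors
retain mirror-region conformations that inflate the maxima by ~7 Å².
The ≥4-bond rule means the 1–4 contacts that carve the fine structure of
the true Ramachandran map are *not* screened, so the steric filter is
intentionally permissive; tight region selection is the job of the
Ramachandran regions below.

With these defaults the 5° scans give theoretical maxima of 103.4 Å²
(Gly), 128.9 Å² (Ala) and 152.1 Å² (Ser) — within ±3 Å² of the published
reference constants (104, 129, 155) — and coarse 20° scans of the other
17 amino acids all land within ~2–12 Å² below their reference values
(coarser grids and idealized sector means bias the maximum slightly low;
cysteine, the most variable reference, is the farthest).

## Ramachandran regions

Empirically, regions are derived per amino acid from (φ, ψ) bin counts
(default 20° bins): bins are ranked by count and the count threshold is
the largest value whose bins cover ≥80% (CORE) or ≥97% (ALLOWED) of
observations; GENEROUS dilates ALLOWED by 20° in the four axis directions
on the torus; ALL is every non-empty bin. CORE ⊆ ALLOWED ⊆ GENEROUS holds
by construction and under property test.

When no corpus is available, an idealized standard-convention mask
(packaged data: rectangle unions for the generic case, mirrored for
glycine, restricted for proline) stands in for region-tagged reporting.
This mask cannot reproduce corpus-specific region boundaries; in
particular, the left- and right-handed helical exposure lobes of alanine
are tied within <1 Å² under the heavy-atom steric filter, and which one
carries the global argmax depends on region boundaries at the level of
single bins. The package therefore reports global (ALL-region) maxima as
its headline theoretical values and treats region-restricted maxima as
corpus-dependent quantities.

## Empirical survey

PDB files (v3.3, ATOM records; HETATM and altloc ≠ 'A' skipped; first
model only) are parsed with gemmi. Per structure: peptide-bond statistics
are computed over all chains; a residue is flagged as chain-terminating
if it is first/last in its chain or adjacent to a peptide bond deviating
>6 SD from the structure mean (a single outlier among m bonds can reach
at most z = √(m−1), so this screen needs chains of ≳38 residues to
fire). A residue is quality-flagged — together with both sequence
neighbours — if any atom occupancy differs from 1.00 exactly as printed,
or any template heavy atom is missing (OXT ignored). Unflagged residues
with both φ and ψ defined contribute observations (φ, ψ, ASA); secondary
structure is retained as a field but populated as "unknown" (nothing is
derived from it). RSA is ASA over the scale maximum, deliberately not
clipped at 1.

The synthetic-corpus generator builds chains with the same geometry
engine (seeded random sequences, conformations drawn from broad
Ramachandran basins, random sector χ), plants occupancy defects and
peptide-bond stretches (translating everything downstream, so only the
one bond is perturbed), writes standard PDB files, and emits a
ground-truth sidecar computed on the coordinates as written (3-decimal
rounding) outside the reading path. It emulates the *bookkeeping* of real
crystallographic data — file format, defects, dihedral/ASA recovery —
but not its physics: no packing, no side-chain/backbone correlations, no
experimental noise, no realistic amino-acid or conformer frequencies.
Passing fixture tests therefore validates the pipeline's correctness
(exact recovery of planted maxima, flags and fractions, byte-identical
reruns), not any biological claim about real corpora; published-corpus
quantities (exceedance frequencies, hydrophobicity correlations) are out
of scope without the original structure set.

## Normalization tables and hydrophobicity

The packaged table carries the four published constant sets (theoretical
and empirical ALLOWED-region maxima, Miller 1987, Rose 1985; 20 entries
each). Percent corrections between scales are 100·(a−b)/a rounded to the
nearest integer, with the first scale as denominator — the only
convention that reproduces both published endpoints (Leu 4%, Asp 18%)
from the table constants.

Hydrophobicity scales: 1 − mean RSA (larger = more hydrophobic);
fraction 100% buried (ASA exactly 0 as the engine reports it); fraction
95% buried (RSA ≤ 0.05 under a chosen scale). Correlations are Pearson
over the 20 amino acids with |r| reported and a p < 0.05 significance
flag, no multiple-testing correction; |r| is invariant under affine
transforms of either scale, so the sign/offset conventions are
immaterial to reported statistics (under test). Two experimental scales
are packaged (Kyte–Doolittle hydropathy, Fauchère–Pliska octanol/water
π); additional scales can be supplied by the user as
`HydrophobicityScale` objects.

## Problem sizes and determinism

Default test and acceptance workloads use 5° grids (5 184 grid points per
amino acid; 15 552 conformations for serine's three χ₁ sectors) and
960-point quadrature, which keeps a full Gly/Ala/Ser reproduction in the
low minutes on one CPU; the 1°-step protocol of the original derivation
is available behind the `step` parameter. All randomness flows from a
single integer seed through NumPy generators; scans of amino acids with
≤10 rotamer combinations are seed-independent.

## Known limitations

* Heavy-atom sterics with the ≥4-bond rule cannot reproduce
  corpus-derived region boundaries; mirror-region (positive-φ)
  conformations of L-residues survive the filter and are excluded only
  by region masks.
* Sector-mean χ values are idealized centres, not library averages;
  this biases side-chain maxima slightly low (≤ a few Å²).
* Bond lengths/angles are fixed at standard means; natural variation
  around them (notably the N-CA-C angle) is not explored.
* No mmCIF input, no PISCES-style culling, no chain-terminator
  normalization values (terminal residues are excluded everywhere).
* DSSP's exact slice-based integration is matched only within quadrature
  tolerance, not bit-for-bit.
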