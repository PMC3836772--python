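"""Exhaustive conformational scans of Gly-X-Gly tripeptides.

For each point of a discrete (phi, psi) grid the central residue is set to
that backbone conformation, every enumerated side-chain rotamer is built,
sterically impossible conformations are discarded, and the central
residue's accessible surface area is recorded.  The per-bin maximum over
rotamers yields a map of maximum ASA as a function of backbone dihedrals;
its maximum over a Ramachandran region gives the normalization constant
for that region.

Rotamers follow the three-sector convention: each chi angle is binned into
the gauche+/gauche-/trans thirds of the circle and represented by a sector
mean.  Amino acids with more than ten distinct sector combinations are
sampled (ten combinations, without replacement) rather than enumerated,
with a fresh draw at every grid point.
"""

from __future__ import annotations

import functools
import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import geometry as geo
from . import sasa as sasa_mod
from .geometry import SideChainConformation, BackboneConformation

__all__ = [
    "RotamerEntry",
    "MaxAsaGrid",
    "sector_means",
    "enumerate_rotamers",
    "steric_clash",
    "nonbonded_pairs",
    "scan_amino_acid",
    "max_asa_in_region",
]

MAX_ROTAMERS = 10


@dataclass(frozen=True)
class RotamerEntry:
    """Sector-mean chi values for one amino acid (one triple per chi)."""

    aa: str
    sector_means: tuple   # tuple over chis of (g+, g-, trans) means


@functools.lru_cache(maxsize=1)
def _sector_data() -> dict:
    with resources.files("maxasa.data").joinpath(
            "rotamer_sectors.json").open() as fh:
        return json.load(fh)


def sector_means(aa: str) -> RotamerEntry:
    """Packaged sector-mean chi values for one amino acid."""
    n_chi = geo.get_template(aa).n_chi
    data = _sector_data()
    default = tuple(data["default_sector_means"])
    per_aa = data.get("per_aa", {}).get(aa)
    if per_aa is not None:
        means = tuple(tuple(m) for m in per_aa)
    else:
        means = (default,) * n_chi
    return RotamerEntry(aa=aa, sector_means=means)


def enumerate_rotamers(aa: str, rng_seed=None,
                       max_rotamers: int = MAX_ROTAMERS) -> list:
    """Side-chain conformations to evaluate for one amino acid.

    All sector combinations when there are at most ``max_rotamers`` of
    them; otherwise ``max_rotamers`` combinations sampled without
    replacement using ``rng_seed``.  Amino acids without chi angles yield a
    single empty conformation.
    """
    entry = sector_means(aa)
    if not entry.sector_means:
        return [SideChainConformation(())]
    combos = list(itertools.product(*entry.sector_means))
    if len(combos) > max_rotamers:
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(combos), size=max_rotamers, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return [SideChainConformation(c) for c in combos]


def nonbonded_pairs(pep: geo.Peptide) -> np.ndarray:
    """Atom-index pairs separated by at least four bonds."""
    n = len(pep.atoms)
    adj = [[] for _ in range(n)]
    for i, j in pep.bond_pairs:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), 99, dtype=int)
    for s in range(n):                       # BFS per atom; n is small
        dist[s, s] = 0
        queue = [s]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if dist[s, v] == 99:
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    ii, jj = np.triu_indices(n, k=1)
    keep = dist[ii, jj] >= 4
    return np.column_stack([ii[keep], jj[keep]])


def steric_clash(pep: geo.Peptide, tolerance_factor: float = 0.85,
                 radii: sasa_mod.RadiusTable | None = None,
                 pairs: np.ndarray | None = None) -> bool:
    """True when any non-bonded pair (>= 4 bonds apart) overlaps.

    A pair clashes when its distance is below ``tolerance_factor`` times
    the sum of the two van der Waals radii.
    """
    radii = radii or sasa_mod.DSSP_RADII
    if pairs is None:
        pairs = nonbonded_pairs(pep)
    if len(pairs) == 0 or tolerance_factor <= 0:
        return False
    coords = pep.coords()
    r = np.array([radii.radius_of(a) for a in pep.atoms])
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    limit = tolerance_factor * (r[pairs[:, 0]] + r[pairs[:, 1]])
    return bool(np.any(d < limit))


@dataclass
class MaxAsaGrid:
    """Per-(phi, psi)-bin maximum ASA for one amino acid.

    ``cells`` maps (phi, psi) bin origins to dicts with the bin maximum
    (``asa``) and the argmax conformation (``phi``, ``psi``, ``chis``).
    """

    aa: str
    bin_width: float
    cells: dict = field(default_factory=dict)

    def bins(self):
        return self.cells.keys()

    def record(self, bin_key, asa, phi, psi, chis):
        cell = self.cells.get(bin_key)
        if cell is None or asa > cell["asa"] + 1e-12:
            self.cells[bin_key] = {
                "asa": asa, "phi": phi, "psi": psi, "chis": tuple(chis)}

    def global_max(self) -> float:
        return max(c["asa"] for c in self.cells.values())

    def global_argmax(self) -> dict:
        # lexicographic (phi, psi) tie-break
        best_key = None
        for key in sorted(self.cells):
            if (best_key is None
                    or self.cells[key]["asa"] > self.cells[best_key]["asa"] + 1e-12):
                best_key = key
        return dict(self.cells[best_key], bin=best_key)

    def to_table(self):
        import pandas as pd
        rows = [
            {"phi_bin": k[0], "psi_bin": k[1], "max_asa": c["asa"],
             "argmax_phi": c["phi"], "argmax_psi": c["psi"],
             "argmax_chis": ",".join(f"{x:g}" for x in c["chis"])}
            for k, c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def scan_amino_acid(aa: str, step: float = 5.0,
                    params: dict | None = None,
                    radii: sasa_mod.RadiusTable | None = None,
                    rng_seed: int = 0,
                    n_points: int = sasa_mod.DEFAULT_N_POINTS,
                    clash_tolerance: float = 0.85,
                    max_rotamers: int = MAX_ROTAMERS,
                    restrict_proline_phi: bool = False) -> MaxAsaGrid:
    """Full (phi, psi) scan of the Gly-``aa``-Gly tripeptide.

    ``step`` must divide 360.  Clashing conformations are discarded; the
    per-bin maximum central-residue ASA and its argmax conformation are
    recorded.  Deterministic for a fixed ``rng_seed``: amino acids whose
    rotamers are subsampled draw a fresh seeded subset at each grid point.
    """
    if abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError("step must divide 360 degrees")
    radii = radii or sasa_mod.DSSP_RADII
    tmpl = geo.get_template(aa)
    n_combos = 3 ** tmpl.n_chi if tmpl.n_chi else 1
    fixed_rotamers = (enumerate_rotamers(aa, rng_seed, max_rotamers)
                      if n_combos <= max_rotamers else None)

    values = np.arange(-180.0, 180.0, step)
    grid = MaxAsaGrid(aa=aa, bin_width=float(step))
    pairs = None
    for i_phi, phi in enumerate(values):
        if (restrict_proline_phi and aa == "P"
                and not (-110.0 <= phi <= -40.0)):
            continue
        for i_psi, psi in enumerate(values):
            if fixed_rotamers is not None:
                rotamers = fixed_rotamers
            else:
                rotamers = enumerate_rotamers(
                    aa, [rng_seed, i_phi, i_psi], max_rotamers)
            bb = BackboneConformation(phi=float(phi), psi=float(psi),
                                      omega=180.0)
            for sc in rotamers:
                pep = geo.build_tripeptide(aa, bb, sc, params=params)
                if pairs is None:
                    pairs = nonbonded_pairs(pep)
                if steric_clash(pep, clash_tolerance, radii, pairs):
                    continue
                asa = sasa_mod.residue_asa(
                    pep, radii=radii, n_points=n_points, residues=[1])[0].asa
                grid.record((float(phi), float(psi)), asa,
                            float(phi), float(psi), sc.chis)
    return grid


@functools.lru_cache(maxsize=1)
def _region_data() -> dict:
    with resources.files("maxasa.data").joinpath(
            "ramachandran_regions.json").open() as fh:
        return json.load(fh)


@functools.lru_cache(maxsize=None)
def standard_region(aa: str, kind: str = "ALLOWED",
                    bin_width: float = 5.0) -> frozenset:
    """Approximate CORE/ALLOWED Ramachandran bin set for one amino acid.

    An idealized stand-in for empirically derived regions (the survey
    module computes those from dihedral counts when a corpus is
    available): unions of rectangles following the standard validation
    conventions, mirrored through the origin for glycine.  Returns the
    set of (phi, psi) bin origins whose centres fall inside the region.
    """
    kind = kind.upper()
    data = _region_data()
    key = "proline" if aa == "P" else "generic"
    if kind == "ALL":
        rects = [[-180, 180, -180, 180]]
    elif kind in ("CORE", "ALLOWED", "GENEROUS"):
        # GENEROUS handled as ALLOWED here; empirical dilation lives in survey
        which = "core" if kind == "CORE" else "allowed"
        rects = list(data[key][which])
        if which == "allowed":
            rects += data[key]["core"]      # enforce CORE subset of ALLOWED
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    mirrored = aa == "G" and key == "generic"
    bins = []
    values = np.arange(-180.0, 180.0, bin_width)
    for phi in values:
        for psi in values:
            cp, cs = phi + bin_width / 2, psi + bin_width / 2
            hit = any(r[0] <= cp <= r[1] and r[2] <= cs <= r[3] for r in rects)
            if not hit and mirrored:
                hit = any(r[0] <= -cp <= r[1] and r[2] <= -cs <= r[3]
                          for r in rects)
            if hit:
                bins.append((phi, psi))
    return frozenset(bins)


def max_asa_in_region(grid: MaxAsaGrid, region) -> float:
    """Maximum ASA over the bins of a Ramachandran region.

    ``region`` is either an iterable of (phi, psi) bin origins or an object
    with a ``bins`` attribute (e.g. a survey RamachandranRegion); ``None``
    means the full grid.
    """
    if region is None:
        return grid.global_max()
    bins = getattr(region, "bins", region)
    values = [grid.cells[b]["asa"] for b in bins if b in grid.cells]
    if not values:
        raise ValueError("region does not intersect the grid")
    return max(values)


def argmax_in_region(grid: MaxAsaGrid, region=None) -> dict:
    """Argmax cell over a region (lexicographic (phi, psi) tie-break)."""
    bins = grid.cells.keys() if region is None else getattr(region, "bins", region)
    best = None
    for b in sorted(b for b in bins if b in grid.cells):
        if best is None or grid.cells[b]["asa"] > grid.cells[best]["asa"] + 1e-12:
            best = b
    if best is None:
        raise ValueError("region does not intersect the grid")
    return dict(grid.cells[best], bin=best)
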