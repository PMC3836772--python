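"""Solvent-accessible surface area by the Lee-Richards probe definition.

The accessible surface of an atom is the locus of the centre of a probe
sphere (default radius 1.4 A, a water molecule) rolled over the molecule's
van der Waals surface.  It is computed numerically in the Shrake-Rupley
manner: quasi-uniform points on each atom's solvent-expanded sphere are
tested for occlusion by the expanded spheres of all other atoms, and the
exposed fraction is multiplied by the expanded sphere's area.

The default radius table matches DSSP: N 1.65, O 1.40, backbone carbonyl
C 1.76, all other C 1.87, S 1.85 A.  Sphere points come from a golden-spiral
(Fibonacci) lattice, so results are deterministic for a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadiusTable",
    "ResidueAsa",
    "DEFAULT_RADII",
    "sphere_points",
    "atom_asa",
    "residue_asa",
]

#: Element-class radii (N 1.65, O 1.40, carbonyl C 1.76, other C 1.87,
#: S 1.85).  Applied to every atom by its radius class.
ELEMENT_RADII = {
    "N": 1.65,
    "O": 1.40,
    "C_carbonyl": 1.76,
    "C_other": 1.87,
    "S": 1.85,
}
DEFAULT_RADII = ELEMENT_RADII

#: Backbone atom names; everything else is a side-chain atom for radius
#: assignment purposes.
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class RadiusTable:
    """van der Waals radii per radius class plus the probe radius (A).

    ``sidechain_radius``, when set, overrides the class radius for every
    atom that is not a backbone atom.  DSSP assigns a single 1.80 A radius
    to all side-chain atoms, so the DSSP-compatible table sets it.
    """

    radii: dict = field(default_factory=lambda: dict(ELEMENT_RADII))
    probe_radius: float = 1.4
    sidechain_radius: float | None = 1.80

    def __post_init__(self):
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius < 0:
            raise ValueError("radii must be positive, probe non-negative")

    def radius_of(self, atom) -> float:
        if (self.sidechain_radius is not None
                and atom.name not in _BACKBONE_NAMES):
            return self.sidechain_radius
        return self.radii[atom.radius_class]


#: The DSSP (Kabsch & Sander) convention: backbone N 1.65, O 1.40,
#: carbonyl C 1.76, CA 1.87; every side-chain atom 1.80; probe 1.4.
DSSP_RADII = RadiusTable()

#: Pure element-class radii with no flat side-chain override.
ELEMENT_RADIUS_TABLE = RadiusTable(sidechain_radius=None)


@dataclass(frozen=True)
class ResidueAsa:
    """Accessible surface area (A^2) of one residue."""

    residue_id: object
    aa: str
    asa: float


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the golden-spiral lattice."""
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_asa(atoms, radii: RadiusTable | None = None,
             n_points: int = DEFAULT_N_POINTS,
             subset=None) -> np.ndarray:
    """Per-atom accessible surface area (A^2).

    ``atoms`` is a sequence of objects with ``coords`` and ``radius_class``.
    When ``subset`` (an index array) is given, areas are computed only for
    those atoms, with every atom still acting as an occluder; the returned
    array then follows the subset's order.
    """
    radii = radii or RadiusTable()
    coords = np.array([a.coords for a in atoms], dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("empty structure")
    r = np.array([radii.radius_of(a) for a in atoms]) + radii.probe_radius

    if len(coords) > 1:
        deltas = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", deltas, deltas)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 1e-12:
            raise ValueError("coincident atoms")
    else:
        d2 = np.full((1, 1), np.inf)

    unit = sphere_points(n_points)
    targets = range(len(coords)) if subset is None else np.atleast_1d(subset)
    out = np.empty(len(list(targets)) if subset is not None else len(coords))
    for k, i in enumerate(targets):
        # occluders: atoms whose expanded sphere can reach atom i's
        near = np.flatnonzero(d2[i] < (r[i] + r) ** 2)
        pts = coords[i] + r[i] * unit
        if near.size:
            diff = pts[:, None, :] - coords[near][None, :, :]
            occluded = np.any(
                np.einsum("pjk,pjk->pj", diff, diff) < r[near] ** 2, axis=1)
            exposed = np.count_nonzero(~occluded)
        else:
            exposed = n_points
        out[k] = 4.0 * np.pi * r[i] ** 2 * exposed / n_points
    return out


def _residue_groups(structure):
    """Normalize input to (residue_id, aa, atom list) triples."""
    if hasattr(structure, "residue_slices"):       # a built Peptide
        return [(i, structure.sequence[i], structure.residue_atoms(i))
                for i in range(structure.n_residues)]
    groups = list(structure)
    if groups and len(groups[0]) != 3:
        raise TypeError("expected a Peptide or (id, aa, atoms) triples")
    return groups


def residue_asa(structure, radii: RadiusTable | None = None,
                n_points: int = DEFAULT_N_POINTS,
                residues=None) -> list:
    """Accessible surface area per residue (sum over its atoms).

    All atoms of the structure occlude; ``residues`` optionally restricts
    which residues' areas are evaluated (indices into the residue list).
    """
    groups = _residue_groups(structure)
    if not groups:
        raise ValueError("empty structure")
    flat = []
    slices = []
    for _, _, atoms in groups:
        start = len(flat)
        flat.extend(atoms)
        slices.append((start, len(flat)))
    wanted = range(len(groups)) if residues is None else residues
    subset = np.concatenate([np.arange(*slices[i]) for i in wanted])
    areas = atom_asa(flat, radii=radii, n_points=n_points, subset=subset)
    out = []
    pos = 0
    for i in wanted:
        s, e = slices[i]
        n = e - s
        rid, aa, _ = groups[i]
        out.append(ResidueAsa(rid, aa, float(areas[pos:pos + n].sum())))
        pos += n
    return out
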