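"""Internal-coordinate peptide construction.

Peptide chains are built atom by atom with the natural-extension reference
frame (NeRF) construction: each new atom is placed at a given bond length,
bond angle and dihedral angle relative to three previously placed atoms.
Backbone geometry comes from a standard (Engh & Huber style) parameter set;
side-chain internal coordinates are derived once per residue type from the
ideal coordinates of the PDB Chemical Component Dictionary, with the
chi-defining torsions exposed as free parameters.

All dihedral angles follow the IUPAC 1970 sign convention and are stored in
degrees in the half-open interval [-180, 180).  Hydrogens are excluded
throughout (heavy-atom convention, as used by DSSP).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomSite",
    "InternalCoordinate",
    "BackboneConformation",
    "SideChainConformation",
    "ResidueTemplate",
    "Peptide",
    "Tripeptide",
    "BACKBONE_PARAMS",
    "CHI_ATOMS",
    "THREE_LETTER",
    "place_atom",
    "bond_angle",
    "dihedral_angle",
    "wrap_angle",
    "get_template",
    "build_chain",
    "build_tripeptide",
    "set_dihedral",
    "measure_dihedral",
    "write_pdb",
]

# ---------------------------------------------------------------------------
# basic types

#: van der Waals radius classes, resolved from atom name + element alone.
#: Only the backbone carbonyl carbon (atom name "C") is in the carbonyl
#: class; every other carbon is "C_other".
RADIUS_CLASSES = ("N", "O", "C_carbonyl", "C_other", "S")


def radius_class_of(name: str, element: str) -> str:
    element = element.upper()
    if element == "N":
        return "N"
    if element == "O":
        return "O"
    if element == "S":
        return "S"
    if element == "C":
        return "C_carbonyl" if name == "C" else "C_other"
    raise ValueError(f"no radius class for element {element!r} (atom {name!r})")


@dataclass
class AtomSite:
    """A single heavy atom: PDB atom name, element, coordinates (A)."""

    name: str
    element: str
    coords: np.ndarray
    radius_class: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite 3-vector")
        if not self.radius_class:
            self.radius_class = radius_class_of(self.name, self.element)


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length (A), bond angle and dihedral (degrees) for NeRF placement."""

    bond_length: float
    bond_angle: float
    dihedral: float

    def __post_init__(self):
        if not self.bond_length > 0:
            raise ValueError("bond length must be positive")
        if not 0 < self.bond_angle < 180:
            raise ValueError("bond angle must lie in (0, 180) degrees")


@dataclass(frozen=True)
class BackboneConformation:
    """Backbone dihedrals phi, psi, omega in degrees."""

    phi: float = -180.0
    psi: float = -180.0
    omega: float = 180.0


@dataclass(frozen=True)
class SideChainConformation:
    """Ordered chi angles in degrees; empty for Gly/Ala/Pro."""

    chis: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "chis", tuple(float(c) for c in self.chis))


# ---------------------------------------------------------------------------
# vector algebra

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise ValueError("zero-length vector in geometric frame")
    return v / n


def wrap_angle(a):
    """Map an angle in degrees onto [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 between p0 and p2, degrees."""
    u = _unit(np.asarray(p0, float) - p1)
    v = _unit(np.asarray(p2, float) - p1)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3, IUPAC convention, degrees in [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def place_atom(a: AtomSite, b: AtomSite, c: AtomSite,
               ic: InternalCoordinate, name: str = "X",
               element: str = "C") -> AtomSite:
    """Place a new atom bonded to ``c`` using NeRF.

    The new atom lies at distance ``ic.bond_length`` from ``c``, forms angle
    ``ic.bond_angle`` with (b, c) and torsion ``ic.dihedral`` with (a, b, c).
    Raises ``ValueError`` when the reference atoms are (near) collinear,
    which leaves the placement frame undefined.
    """
    pa, pb, pc = a.coords, b.coords, c.coords
    coords = _nerf(pa, pb, pc, ic.bond_length, ic.bond_angle, ic.dihedral)
    return AtomSite(name=name, element=element, coords=coords)


def _nerf(pa, pb, pc, length, angle, torsion):
    bc = _unit(pc - pb)
    ab = pb - pa
    n_raw = np.cross(ab, bc)
    n_norm = np.linalg.norm(n_raw)
    if n_norm < 1e-8:
        raise ValueError("collinear reference atoms: placement frame degenerate")
    n = n_raw / n_norm
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d = length * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return pc + d[0] * bc + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# residue templates (side chains from CCD ideal geometry)

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

#: Standard side-chain torsion definitions.  Proline's ring torsions are not
#: free parameters here: the ring is kept in a fixed endocyclic template
#: geometry, so proline carries no adjustable chi angle.
CHI_ATOMS = {
    "A": [], "G": [], "P": [],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
}

#: Default backbone geometry (Engh & Huber style restraint values).
#: Exposed as data so that an alternative set (e.g. averages mined from a
#: structure corpus by the survey module) can be substituted.
BACKBONE_PARAMS = {
    "len_n_ca": 1.458,
    "len_ca_c": 1.525,
    "len_c_o": 1.231,
    "len_c_n": 1.329,   # trans peptide bond
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}


@dataclass(frozen=True)
class _BuildRecord:
    """One side-chain atom's NeRF placement rule.

    ``torsion_ref`` names a chi parameter ("chi1" ...); the actual torsion
    applied is that parameter plus ``torsion`` (a constant branch offset).
    With ``torsion_ref=None`` the torsion is the fixed template value.
    """

    name: str
    element: str
    frame: tuple
    bond_length: float
    bond_angle: float
    torsion: float
    torsion_ref: str | None = None


@dataclass(frozen=True)
class ResidueTemplate:
    """Heavy-atom topology and internal coordinates for one residue type."""

    aa: str
    resname: str
    sidechain: tuple            # tuple of _BuildRecord, in build order
    chi_defs: tuple             # tuple of 4-tuples of atom names
    bonds: tuple                # heavy-atom bonds as (name, name) pairs

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    @property
    def atom_names(self) -> tuple:
        return ("N", "CA", "C", "O") + tuple(r.name for r in self.sidechain)


@functools.lru_cache(maxsize=None)
def get_template(aa: str) -> ResidueTemplate:
    """Side-chain template for one amino acid, derived from CCD ideal geometry."""
    if aa not in THREE_LETTER:
        raise ValueError(f"unknown amino acid {aa!r}")
    import biotite.structure.info as struc_info

    resname = THREE_LETTER[aa]
    ideal = struc_info.residue(resname)
    heavy = ideal[(ideal.element != "H") & (ideal.atom_name != "OXT")]
    names = list(heavy.atom_name)
    coords = {n: heavy.coord[i] for i, n in enumerate(names)}

    # heavy-atom bond list from the CCD
    bonds = []
    idx_of = {n: i for i, n in enumerate(names)}
    all_names = list(ideal.atom_name)
    for i, j, _ in ideal.bonds.as_array():
        ni, nj = all_names[i], all_names[j]
        if ni in idx_of and nj in idx_of:
            bonds.append(tuple(sorted((ni, nj))))
    bonds = sorted(set(bonds))

    adjacency = {n: [] for n in names}
    for ni, nj in bonds:
        adjacency[ni].append(nj)
        adjacency[nj].append(ni)

    # BFS over the side chain starting at CB; parent chain seeds the frames
    chi_defs = tuple(CHI_ATOMS[aa])
    records = []
    if "CB" in idx_of:
        parent = {"CB": "CA", "CA": "N"}
        order = ["CB"]
        queue = ["CB"]
        seen = {"N", "CA", "C", "O", "CB"}
        while queue:
            p = queue.pop(0)
            for nb in sorted(adjacency[p], key=names.index):
                if nb in seen:
                    continue
                parent[nb] = p
                seen.add(nb)
                order.append(nb)
                queue.append(nb)

        chi_by_frame = {tuple(cd[:3]): (k, cd[3]) for k, cd in enumerate(chi_defs)}
        for atom in order:
            el = heavy.element[idx_of[atom]]
            if atom == "CB":
                # improper torsion relative to the backbone: chirality-fixing
                frame = ("C", "N", "CA")
                tor = dihedral_angle(coords["C"], coords["N"],
                                     coords["CA"], coords["CB"])
                rec = _BuildRecord("CB", el, frame,
                                   float(np.linalg.norm(coords["CB"] - coords["CA"])),
                                   bond_angle(coords["N"], coords["CA"], coords["CB"]),
                                   tor)
            else:
                p = parent[atom]
                g = parent[p]
                gg = parent[g]
                frame = (gg, g, p)
                tor = dihedral_angle(coords[gg], coords[g], coords[p], coords[atom])
                ref = None
                if frame in chi_by_frame:
                    k, chi_atom = chi_by_frame[frame]
                    ref = f"chi{k + 1}"
                    chi_ideal = dihedral_angle(coords[frame[0]], coords[frame[1]],
                                               coords[frame[2]], coords[chi_atom])
                    tor = float(wrap_angle(tor - chi_ideal))
                rec = _BuildRecord(atom, el, frame,
                                   float(np.linalg.norm(coords[atom] - coords[p])),
                                   bond_angle(coords[g], coords[p], coords[atom]),
                                   float(wrap_angle(tor)), ref)
            records.append(rec)

    return ResidueTemplate(aa=aa, resname=resname, sidechain=tuple(records),
                           chi_defs=chi_defs, bonds=tuple(bonds))


# ---------------------------------------------------------------------------
# chains

@dataclass
class Peptide:
    """A built peptide chain: flat atom list plus residue bookkeeping."""

    sequence: str
    atoms: list = field(default_factory=list)
    residue_slices: list = field(default_factory=list)   # (start, stop) per residue
    dihedral_index: dict = field(default_factory=dict)   # name -> 4 atom indices
    bond_pairs: list = field(default_factory=list)       # (i, j) atom-index bonds

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def residue_atoms(self, i: int) -> list:
        s, e = self.residue_slices[i]
        return self.atoms[s:e]

    def atom_index(self, res: int, name: str) -> int:
        s, e = self.residue_slices[res]
        for i in range(s, e):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"atom {name!r} not in residue {res}")

    @property
    def n_residues(self) -> int:
        return len(self.residue_slices)


class Tripeptide(Peptide):
    """Gly-X-Gly tripeptide; the central residue X is residue index 1.

    Bare dihedral names ("phi", "psi", "omega", "chi1", ...) refer to the
    central residue.
    """

    @property
    def central_aa(self) -> str:
        return self.sequence[1]

    def central_atoms(self) -> list:
        return self.residue_atoms(1)


def _resolve_torsion(rec: _BuildRecord, chis: tuple) -> float:
    if rec.torsion_ref is None:
        return rec.torsion
    k = int(rec.torsion_ref[3:]) - 1
    return float(wrap_angle(chis[k] + rec.torsion))


def build_chain(sequence: str,
                backbones: list | None = None,
                sidechains: list | None = None,
                params: dict | None = None,
                cls=Peptide) -> Peptide:
    """Construct a full peptide chain from internal coordinates.

    ``backbones`` and ``sidechains`` give one :class:`BackboneConformation`
    and one :class:`SideChainConformation` per residue (defaults: extended
    backbone, template chi values of 180/ideal).  The first residue has no
    phi; the last residue's psi only orients its carbonyl oxygen.
    """
    p = dict(BACKBONE_PARAMS)
    if params:
        p.update(params)
    n = len(sequence)
    if n < 1:
        raise ValueError("empty sequence")
    backbones = list(backbones) if backbones else [BackboneConformation()] * n
    if len(backbones) != n:
        raise ValueError("need one backbone conformation per residue")
    templates = [get_template(aa) for aa in sequence]
    if sidechains is None:
        sidechains = [SideChainConformation((180.0,) * t.n_chi) for t in templates]
    sidechains = list(sidechains)
    if len(sidechains) != n:
        raise ValueError("need one side-chain conformation per residue")
    for t, sc in zip(templates, sidechains):
        if len(sc.chis) != t.n_chi:
            raise ValueError(
                f"{t.aa}: expected {t.n_chi} chi angles, got {len(sc.chis)}")

    pep = cls(sequence=sequence)
    pos: list[dict] = []       # per-residue name -> coords

    for i, (tmpl, bb, sc) in enumerate(zip(templates, backbones, sidechains)):
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([p["len_n_ca"], 0.0, 0.0])
            ang = np.radians(p["ang_n_ca_c"])
            res["C"] = res["CA"] + p["len_ca_c"] * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = pos[i - 1]
            res["N"] = _nerf(prev["N"], prev["CA"], prev["C"],
                             p["len_c_n"], p["ang_ca_c_n"], backbones[i - 1].psi)
            res["CA"] = _nerf(prev["CA"], prev["C"], res["N"],
                              p["len_n_ca"], p["ang_c_n_ca"], bb.omega)
            res["C"] = _nerf(prev["C"], res["N"], res["CA"],
                             p["len_ca_c"], p["ang_n_ca_c"], bb.phi)
        res["O"] = _nerf(res["N"], res["CA"], res["C"],
                         p["len_c_o"], p["ang_ca_c_o"], wrap_angle(bb.psi + 180.0))
        for rec in tmpl.sidechain:
            a, b, c = (res[x] for x in rec.frame)
            res[rec.name] = _nerf(a, b, c, rec.bond_length, rec.bond_angle,
                                  _resolve_torsion(rec, sc.chis))
        pos.append(res)

        start = len(pep.atoms)
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            pep.atoms.append(AtomSite(name, el, res[name]))
        for rec in tmpl.sidechain:
            pep.atoms.append(AtomSite(rec.name, rec.element, res[rec.name]))
        pep.residue_slices.append((start, len(pep.atoms)))

    _index_dihedrals(pep, templates)
    _index_bonds(pep, templates)
    return pep


def _index_dihedrals(pep: Peptide, templates) -> None:
    n = pep.n_residues
    ai = pep.atom_index
    for i in range(n):
        r = i + 1
        if i > 0:
            pep.dihedral_index[f"phi{r}"] = (
                ai(i - 1, "C"), ai(i, "N"), ai(i, "CA"), ai(i, "C"))
            pep.dihedral_index[f"omega{r}"] = (
                ai(i - 1, "CA"), ai(i - 1, "C"), ai(i, "N"), ai(i, "CA"))
        if i < n - 1:
            pep.dihedral_index[f"psi{r}"] = (
                ai(i, "N"), ai(i, "CA"), ai(i, "C"), ai(i + 1, "N"))
        for k, cd in enumerate(templates[i].chi_defs):
            pep.dihedral_index[f"chi{k + 1}_{r}"] = tuple(
                ai(i, nm) for nm in cd)
    # central-residue aliases for tripeptides
    if n == 3:
        for short, long in (("phi", "phi2"), ("psi", "psi2"), ("omega", "omega2")):
            if long in pep.dihedral_index:
                pep.dihedral_index[short] = pep.dihedral_index[long]
        for k in range(len(templates[1].chi_defs)):
            pep.dihedral_index[f"chi{k + 1}"] = pep.dihedral_index[f"chi{k + 1}_2"]


def _index_bonds(pep: Peptide, templates) -> None:
    pairs = set()
    for i, tmpl in enumerate(templates):
        have = {a.name for a in pep.residue_atoms(i)}
        for nm1, nm2 in (("N", "CA"), ("CA", "C"), ("C", "O")):
            pairs.add((pep.atom_index(i, nm1), pep.atom_index(i, nm2)))
        for nm1, nm2 in tmpl.bonds:
            if nm1 in have and nm2 in have and {nm1, nm2} - {"N", "CA", "C", "O"}:
                pairs.add(tuple(sorted((pep.atom_index(i, nm1),
                                        pep.atom_index(i, nm2)))))
        if i > 0:
            pairs.add((pep.atom_index(i - 1, "C"), pep.atom_index(i, "N")))
    pep.bond_pairs = sorted(pairs)


def build_tripeptide(aa: str,
                     backbone: BackboneConformation | None = None,
                     sidechain: SideChainConformation | None = None,
                     params: dict | None = None,
                     flank: BackboneConformation | None = None) -> Tripeptide:
    """Build a Gly-``aa``-Gly tripeptide with the given central conformation.

    The flanking glycines default to the extended conformation; only their
    backbone carbonyl/amide orientations influence the central residue.
    """
    if aa not in THREE_LETTER:
        raise ValueError(f"unknown amino acid {aa!r}")
    backbone = backbone or BackboneConformation()
    tmpl = get_template(aa)
    if sidechain is None:
        sidechain = SideChainConformation((180.0,) * tmpl.n_chi)
    if len(sidechain.chis) != tmpl.n_chi:
        raise ValueError(f"{aa}: expected {tmpl.n_chi} chi angles, "
                         f"got {len(sidechain.chis)}")
    flank = flank or BackboneConformation(phi=-180.0, psi=-180.0, omega=180.0)
    empty = SideChainConformation(())
    pep = build_chain("G" + aa + "G",
                      backbones=[flank, backbone, flank],
                      sidechains=[empty, sidechain, empty],
                      params=params, cls=Tripeptide)
    return pep


# ---------------------------------------------------------------------------
# dihedral measurement and adjustment

def measure_dihedral(pep: Peptide, name: str) -> float:
    """Current value of a named dihedral, degrees in [-180, 180)."""
    if name not in pep.dihedral_index:
        raise KeyError(f"unknown dihedral {name!r}")
    ia, ib, ic, id_ = pep.dihedral_index[name]
    c = pep.atoms
    return dihedral_angle(c[ia].coords, c[ib].coords, c[ic].coords, c[id_].coords)


def _moving_set(pep: Peptide, ib: int, ic: int) -> set:
    """Atoms reachable from ``ic`` without traversing ``ib``.

    Traversal avoids the pivot atom entirely, so ring systems through the
    pivot (e.g. the proline ring around N-CA) rotate as a rigid unit.
    """
    adj: dict[int, list] = {}
    for i, j in pep.bond_pairs:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    seen = {ib, ic}
    queue = [ic]
    moving = set()
    while queue:
        u = queue.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                moving.add(v)
                queue.append(v)
    return moving


def set_dihedral(pep: Peptide, name: str, value: float) -> Peptide:
    """Rotate about a named dihedral so that it takes ``value`` (degrees).

    Pure rigid-body rotation of the distal side: every bond length and bond
    angle, and every atom on the proximal side, is left untouched.
    """
    if name not in pep.dihedral_index:
        raise KeyError(f"unknown dihedral {name!r}")
    ia, ib, ic, id_ = pep.dihedral_index[name]
    current = measure_dihedral(pep, name)
    delta = np.radians(wrap_angle(value - current))
    if abs(delta) < 1e-14:
        return pep
    axis_origin = pep.atoms[ib].coords
    axis = _unit(pep.atoms[ic].coords - axis_origin)
    moving = _moving_set(pep, ib, ic)
    if id_ not in moving:
        raise ValueError(f"dihedral {name!r}: distal atom not rotatable")
    # Rodrigues rotation about the b->c axis
    ct, st = np.cos(delta), np.sin(delta)
    for i in moving:
        v = pep.atoms[i].coords - axis_origin
        pep.atoms[i].coords = axis_origin + (
            v * ct + np.cross(axis, v) * st + axis * (axis @ v) * (1 - ct))
    return pep


# ---------------------------------------------------------------------------
# PDB output

def write_pdb(pep: Peptide, path, chain_id: str = "A",
              occupancies: dict | None = None) -> None:
    """Write a single-model PDB v3.3 file (ATOM records only).

    ``occupancies`` optionally maps (residue_index, atom_name) to an
    occupancy value; everything else is written with occupancy 1.00 and
    B-factor 0.00.
    """
    lines = []
    serial = 0
    for i in range(pep.n_residues):
        resname = THREE_LETTER[pep.sequence[i]]
        for atom in pep.residue_atoms(i):
            serial += 1
            occ = 1.0
            if occupancies:
                occ = occupancies.get((i, atom.name), 1.0)
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {resname:>3s} {chain_id}"
                f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
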