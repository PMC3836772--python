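"""Empirical maximum-ASA survey over a corpus of PDB structures.

Mirrors the quality-controlled mining protocol used to calibrate
normalization scales against real crystal structures:

* chain-terminating residues are excluded (chain ends, plus any residue
  whose peptide bond deviates more than six standard deviations from the
  structure's mean peptide-bond length);
* residues with missing heavy atoms or ambiguous occupancy (any atom with
  occupancy printed as something other than 1.00) are excluded together
  with their immediate sequence neighbours;
* surviving residues contribute (phi, psi, ASA) observations, which are
  binned on the Ramachandran torus; per-amino-acid CORE/ALLOWED/GENEROUS/
  ALL regions are derived from the bin counts, and per-region maximum ASA
  values form the empirical normalization scale.

A synthetic-corpus generator is included for testing: it emits small valid
PDB files (built by the geometry module) with configurable planted
conformations, occupancy defects and bond-length outliers, alongside a
ground-truth sidecar computed independently of the reading pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import sasa as sasa_mod
from .scan import MaxAsaGrid

__all__ = [
    "ResidueObservation",
    "RamachandranRegion",
    "load_structure",
    "flag_chain_terminators",
    "flag_quality",
    "collect_observations",
    "bin_origin",
    "define_regions",
    "empirical_max_grid",
    "rsa",
    "rsa_exceedance_report",
    "generate_corpus",
]

DEFAULT_BIN_WIDTH = 20.0
GENEROUS_EXTENSION = 20.0

OBS_COLUMNS = ["structure", "chain", "position", "aa", "phi", "psi", "asa",
               "secondary_structure", "flag_terminal", "flag_quality"]


@dataclass(frozen=True)
class ResidueObservation:
    structure: str
    chain: str
    position: int
    aa: str
    phi: float
    psi: float
    asa: float
    secondary_structure: str = "unknown"
    flag_terminal: bool = False
    flag_quality: bool = False


@dataclass(frozen=True)
class RamachandranRegion:
    """A set of (phi, psi) bins for one amino acid."""

    aa: str
    kind: str                   # CORE | ALLOWED | GENEROUS | ALL
    bins: frozenset
    count_threshold: int = 0


# ---------------------------------------------------------------------------
# PDB input

def load_structure(path):
    """Parse one PDB file into chains of residues.

    Returns ``{chain_id: [residue, ...]}`` where each residue is a dict
    with ``resseq``, ``aa``, ``atoms`` (list of AtomSite) and
    ``occupancies`` (per atom).  HETATM records, waters and altloc
    conformers other than '' or 'A' are skipped, as are non-standard
    residues.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains = {}
    for model in st:
        for chain in model:
            residues = []
            for res in chain:
                if res.het_flag != "A":
                    continue
                aa = geo.ONE_LETTER.get(res.name)
                if aa is None:
                    continue
                atoms, occs = [], []
                for atom in res:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    if atom.element.name == "H":
                        continue
                    try:
                        site = geo.AtomSite(atom.name, atom.element.name,
                                            np.array(atom.pos.tolist()))
                    except ValueError:
                        continue
                    atoms.append(site)
                    occs.append(float(atom.occ))
                if atoms:
                    residues.append({"resseq": res.seqid.num, "aa": aa,
                                     "atoms": atoms, "occupancies": occs})
            if residues:
                chains[chain.name] = residues
        break       # first model only
    return chains


def _atom(res, name):
    for a in res["atoms"]:
        if a.name == name:
            return a
    return None


def _peptide_bonds(residues):
    """C(i)-N(i+1) distances; NaN when either atom is missing."""
    out = []
    for r1, r2 in zip(residues, residues[1:]):
        c, n = _atom(r1, "C"), _atom(r2, "N")
        out.append(np.linalg.norm(c.coords - n.coords)
                   if c is not None and n is not None else np.nan)
    return np.array(out)


# ---------------------------------------------------------------------------
# quality filters

def flag_chain_terminators(residues, mean: float | None = None,
                           sd: float | None = None,
                           n_sd: float = 6.0) -> set:
    """Indices of chain-terminating residues in one chain.

    The first and last residues are always flagged.  Additionally, any
    residue adjacent to a peptide bond whose length deviates more than
    ``n_sd`` standard deviations from the mean peptide-bond length is
    flagged.  ``mean``/``sd`` default to this chain's own bond statistics
    (pass structure-wide values to reproduce whole-structure screening);
    a zero standard deviation yields no additional flags.  Chains with
    fewer than three residues are flagged entirely.
    """
    n = len(residues)
    if n < 3:
        return set(range(n))
    flagged = {0, n - 1}
    bonds = _peptide_bonds(residues)
    finite = bonds[np.isfinite(bonds)]
    if mean is None:
        mean = float(finite.mean()) if finite.size else 0.0
    if sd is None:
        sd = float(finite.std()) if finite.size else 0.0
    if sd > 0:
        for i, b in enumerate(bonds):
            if np.isfinite(b) and abs(b - mean) > n_sd * sd:
                flagged.update({i, i + 1})
    return flagged


def flag_quality(residues) -> set:
    """Indices of residues with missing atoms or ambiguous occupancy.

    A residue is defective when any atom's occupancy differs from 1.0 or
    any template heavy atom is absent (the C-terminal OXT is ignored).
    Defective residues are flagged together with both sequence
    neighbours.
    """
    defective = set()
    for i, res in enumerate(residues):
        if any(o != 1.0 for o in res["occupancies"]):
            defective.add(i)
            continue
        expected = set(geo.get_template(res["aa"]).atom_names)
        present = {a.name for a in res["atoms"]}
        if expected - present:
            defective.add(i)
    flagged = set()
    for i in defective:
        flagged.update({i - 1, i, i + 1})
    return {i for i in flagged if 0 <= i < len(residues)}


# ---------------------------------------------------------------------------
# observation table

def collect_observations(paths, radii: sasa_mod.RadiusTable | None = None,
                         n_points: int = sasa_mod.DEFAULT_N_POINTS,
                         ) -> pd.DataFrame:
    """Mine per-residue (phi, psi, ASA) observations from PDB files.

    ``paths`` is a directory or an iterable of file paths.  Residues
    lacking a neighbour needed for phi or psi are excluded (consistent
    with terminal exclusion).  Flagged residues stay in the table with
    their flag columns set; downstream statistics use only unflagged
    rows (see :func:`unflagged`).
    """
    radii = radii or sasa_mod.DSSP_RADII
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.pdb"))
    rows = []
    for path in paths:
        path = Path(path)
        chains = load_structure(path)
        # structure-wide peptide-bond statistics for terminator screening
        all_bonds = np.concatenate(
            [_peptide_bonds(res) for res in chains.values()]) if chains else []
        finite = np.asarray(all_bonds)[np.isfinite(all_bonds)]
        mean = float(finite.mean()) if len(finite) else 0.0
        sd = float(finite.std()) if len(finite) else 0.0
        # ASA with every atom of the structure as occluding context
        groups = [((chain_id, i), r["aa"], r["atoms"])
                  for chain_id, residues in sorted(chains.items())
                  for i, r in enumerate(residues)]
        asa_by_idx = {ra.residue_id: ra.asa
                      for ra in sasa_mod.residue_asa(groups, radii=radii,
                                                     n_points=n_points)}
        for chain_id, residues in sorted(chains.items()):
            term = flag_chain_terminators(residues, mean=mean, sd=sd)
            qual = flag_quality(residues)
            for i, res in enumerate(residues):
                phi = psi = np.nan
                n_at, ca, c = (_atom(res, x) for x in ("N", "CA", "C"))
                if None in (n_at, ca, c):
                    continue
                if i > 0:
                    prev_c = _atom(residues[i - 1], "C")
                    if prev_c is not None:
                        phi = geo.dihedral_angle(prev_c.coords, n_at.coords,
                                                 ca.coords, c.coords)
                if i < len(residues) - 1:
                    next_n = _atom(residues[i + 1], "N")
                    if next_n is not None:
                        psi = geo.dihedral_angle(n_at.coords, ca.coords,
                                                 c.coords, next_n.coords)
                if not (np.isfinite(phi) and np.isfinite(psi)):
                    continue
                rows.append((path.stem, chain_id, res["resseq"], res["aa"],
                             phi, psi, asa_by_idx[(chain_id, i)], "unknown",
                             i in term, i in qual))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def unflagged(obs: pd.DataFrame) -> pd.DataFrame:
    return obs[~obs.flag_terminal & ~obs.flag_quality]


# ---------------------------------------------------------------------------
# Ramachandran binning and regions

def bin_origin(angle, width: float = DEFAULT_BIN_WIDTH):
    """Origin of the torus bin containing ``angle`` (degrees)."""
    a = geo.wrap_angle(angle)
    return np.floor(a / width) * width


def bin_counts(obs: pd.DataFrame, aa: str,
               bin_width: float = DEFAULT_BIN_WIDTH) -> dict:
    sub = unflagged(obs)
    sub = sub[sub.aa == aa]
    counts: dict = {}
    for phi, psi in zip(sub.phi, sub.psi):
        key = (float(bin_origin(phi, bin_width)),
               float(bin_origin(psi, bin_width)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def define_regions(counts: dict, aa: str = "X",
                   coverage: float = 0.97,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   extension: float = GENEROUS_EXTENSION,
                   kind: str = "ALLOWED") -> RamachandranRegion:
    """Derive a Ramachandran region from per-bin observation counts.

    Bins are ranked by count; the count threshold is the largest value
    such that all bins at or above it cover at least ``coverage`` of the
    observations (CORE uses 0.80, ALLOWED 0.97).  GENEROUS dilates the
    ALLOWED region by ``extension`` degrees in the four axis directions
    on the torus; ALL is every non-empty bin.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no observations")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    kind = kind.upper()
    if kind == "ALL":
        return RamachandranRegion(aa, "ALL", frozenset(counts), 1)
    if kind == "GENEROUS":
        allowed = define_regions(counts, aa, coverage, bin_width,
                                 extension, kind="ALLOWED")
        bins = set(allowed.bins)
        steps = int(round(extension / bin_width))
        for _ in range(steps):
            grown = set(bins)
            for p, s in bins:
                for dp, ds in ((bin_width, 0), (-bin_width, 0),
                               (0, bin_width), (0, -bin_width)):
                    grown.add((float(geo.wrap_angle(p + dp)),
                               float(geo.wrap_angle(s + ds))))
            bins = grown
        return RamachandranRegion(aa, "GENEROUS", frozenset(bins),
                                  allowed.count_threshold)
    distinct = sorted(set(counts.values()), reverse=True)
    threshold = distinct[-1]
    for t in distinct:
        covered = sum(c for c in counts.values() if c >= t)
        if covered >= coverage * total:
            threshold = t
            break
    bins = frozenset(b for b, c in counts.items() if c >= threshold)
    return RamachandranRegion(aa, kind, bins, threshold)


def empirical_max_grid(obs: pd.DataFrame, aa: str,
                       bin_width: float = DEFAULT_BIN_WIDTH) -> MaxAsaGrid:
    """Per-bin maximum observed ASA for one amino acid (unflagged rows)."""
    sub = unflagged(obs)
    sub = sub[sub.aa == aa]
    if sub.empty:
        raise ValueError(f"no observations for {aa}")
    grid = MaxAsaGrid(aa=aa, bin_width=float(bin_width))
    for phi, psi, asa in zip(sub.phi, sub.psi, sub.asa):
        key = (float(bin_origin(phi, bin_width)),
               float(bin_origin(psi, bin_width)))
        grid.record(key, float(asa), float(phi), float(psi), ())
    return grid


# ---------------------------------------------------------------------------
# RSA

def rsa(asa: float, aa: str, scale) -> float:
    """Relative solvent accessibility: ASA over the scale's maximum ASA.

    Not clipped: values above 1 indicate the scale fails to bound the
    observation.
    """
    values = getattr(scale, "values_by_aa", scale)
    if aa not in values:
        raise KeyError(f"{aa!r} missing from normalization scale")
    if asa < 0:
        raise ValueError("negative ASA")
    return float(asa) / float(values[aa])


def rsa_exceedance_report(obs: pd.DataFrame, scales: dict) -> pd.DataFrame:
    """Per-amino-acid fraction of unflagged residues with RSA > 1.

    ``scales`` maps scale names to normalization scales; one column per
    scale, indexed by amino acid.
    """
    sub = unflagged(obs)
    out = {}
    for name, scale in scales.items():
        values = getattr(scale, "values_by_aa", scale)
        col = {}
        for aa, group in sub.groupby("aa"):
            col[aa] = float(np.mean(group.asa / values[aa] > 1.0))
        out[name] = col
    return pd.DataFrame(out).sort_index()


# ---------------------------------------------------------------------------
# synthetic corpus generator

def generate_corpus(out_dir, n_structures: int = 3, n_residues: int = 12,
                    seed: int = 0, occupancy_defects: int = 0,
                    bond_outliers: int = 0, outlier_stretch: float = 2.0,
                    radii: sasa_mod.RadiusTable | None = None,
                    n_points: int = sasa_mod.DEFAULT_N_POINTS) -> dict:
    """Emit a small synthetic PDB corpus with known ground truth.

    Chains of ``n_residues`` random residues in random plausible
    conformations are built from internal coordinates and written as PDB
    files.  Optionally, ``occupancy_defects`` residues per structure get
    one atom with occupancy 0.50, and ``bond_outliers`` peptide bonds are
    stretched by ``outlier_stretch`` Angstroms (every atom downstream is
    translated, so all other internal geometry is preserved).

    Returns the ground truth: per structure, the planted defect
    positions, the expected flagged residue indices and, for every
    residue, (phi, psi, ASA) computed directly on the coordinates as
    written (i.e. after 3-decimal rounding), independent of the PDB
    reading path.  The same dictionary is written as ``truth.json``.
    """
    radii = radii or sasa_mod.DSSP_RADII
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aas = list(geo.THREE_LETTER)
    basins = [(-60.0, -45.0), (-120.0, 130.0), (-75.0, 150.0), (-90.0, 0.0)]
    truth: dict = {"structures": {}}

    for s in range(n_structures):
        name = f"synth{s:03d}"
        seq = "".join(rng.choice(aas, size=n_residues))
        backbones = []
        sidechains = []
        for aa in seq:
            base = basins[rng.integers(len(basins))]
            phi = float(geo.wrap_angle(base[0] + rng.uniform(-15, 15)))
            psi = float(geo.wrap_angle(base[1] + rng.uniform(-15, 15)))
            backbones.append(geo.BackboneConformation(phi, psi, 180.0))
            n_chi = geo.get_template(aa).n_chi
            sidechains.append(geo.SideChainConformation(
                tuple(rng.choice([-60.0, 60.0, 180.0], size=n_chi))))
        pep = geo.build_chain(seq, backbones, sidechains)

        stretched = sorted(rng.choice(
            np.arange(1, n_residues - 1), size=bond_outliers,
            replace=False)) if bond_outliers else []
        for k in stretched:     # stretch bond C(k-1)..N(k), 0-based residue k
            c = pep.atoms[pep.atom_index(k - 1, "C")].coords
            n = pep.atoms[pep.atom_index(k, "N")].coords
            shift = (n - c) / np.linalg.norm(n - c) * outlier_stretch
            for i in range(pep.residue_slices[k][0], len(pep.atoms)):
                pep.atoms[i].coords = pep.atoms[i].coords + shift

        defect_positions = sorted(rng.choice(
            np.arange(n_residues), size=occupancy_defects,
            replace=False)) if occupancy_defects else []
        occupancies = {}
        for k in defect_positions:
            atom_names = [a.name for a in pep.residue_atoms(int(k))]
            occupancies[(int(k), atom_names[-1])] = 0.5

        geo.write_pdb(pep, out_dir / f"{name}.pdb", occupancies=occupancies)

        # ground truth on the coordinates as written (3-decimal rounding)
        for atom in pep.atoms:
            atom.coords = np.round(atom.coords, 3)
        groups = [(i, seq[i], pep.residue_atoms(i))
                  for i in range(pep.n_residues)]
        asa = {ra.residue_id: ra.asa
               for ra in sasa_mod.residue_asa(groups, radii=radii,
                                              n_points=n_points)}
        residues = []
        for i in range(pep.n_residues):
            entry = {"aa": seq[i], "asa": asa[i]}
            if 0 < i:
                entry["phi"] = geo.measure_dihedral(pep, f"phi{i + 1}")
            if i < pep.n_residues - 1:
                entry["psi"] = geo.measure_dihedral(pep, f"psi{i + 1}")
            residues.append(entry)

        expected_flags = {0, n_residues - 1}
        for k in stretched:
            expected_flags.update({int(k) - 1, int(k)})
        for k in defect_positions:
            expected_flags.update({int(k) - 1, int(k), int(k) + 1})
        expected_flags = sorted(f for f in expected_flags
                                if 0 <= f < n_residues)

        truth["structures"][name] = {
            "sequence": seq,
            "occupancy_defects": [int(k) for k in defect_positions],
            "bond_outliers": [int(k) for k in stretched],
            "expected_flagged": expected_flags,
            "residues": residues,
        }

    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
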