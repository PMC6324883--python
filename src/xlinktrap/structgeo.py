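"""Coordinate I/O and geometric primitives for cysteine cross-linking calibration.

This module covers the structure-side half of the cross-linker ruler approach:
modelling a cysteine at an arbitrary site (single-atom SG placement on the
existing backbone, canonical rotamer), measuring SG-SG distances between
engineered sites, dimer centre-of-mass separations, Shrake-Rupley solvent
accessibility, and steric-clash counting between rigid groups.

Structures are read from fixed-column PDB text through gemmi; coordinates are
kept in plain numpy arrays so that rigid-body operations and accessibility
scans stay vectorised.  mmCIF, multi-model handling beyond the first model,
and altlocs other than ''/'A' are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

# Van der Waals radii (A).  Fixed, documented table; override via the
# ``radii`` argument of read_structure for non-default behaviour.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

# Atomic masses for the optional mass-weighted centroid.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974}

PROBE_RADIUS = 1.4  # water probe, A

# Ideal cysteine side-chain internal coordinates for SG placement:
# bond CB-SG, angle CA-CB-SG, and the modal chi1 dihedral N-CA-CB-SG.
SG_BOND = 1.81
SG_ANGLE = 114.0
SG_CHI1 = -65.0

BACKBONE = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Malformed fixed-column PDB record."""


class SiteError(ValueError):
    """A residue selector does not resolve as required."""


@dataclass(frozen=True)
class ResidueSelector:
    """Identifies one residue by chain id and author residue number."""

    chain: str
    residue_number: int

    def __str__(self) -> str:
        return f"{self.chain}:{self.residue_number}"


@dataclass
class Structure:
    """An ordered atom collection with chain/residue identity.

    All per-atom attributes are parallel arrays of length ``n_atoms``.
    ``subunit_roles`` optionally labels chains as proximal (A/C-like),
    distal (B/D-like), auxiliary, or other.
    """

    element: np.ndarray        # str
    name: np.ndarray           # atom name, str
    residue_number: np.ndarray  # int
    residue_name: np.ndarray   # str
    chain: np.ndarray          # str
    coords: np.ndarray         # (n, 3) float, A
    vdw_radius: np.ndarray     # float, A
    subunit_roles: dict = field(default_factory=dict)
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self) == 0:
            raise ValueError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw_radius <= 0):
            raise ValueError("vdw radii must be positive")
        missing = set(self.subunit_roles) - set(self.chains())
        if missing:
            raise ValueError(f"subunit_roles reference absent chains: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c, None)
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(self.element.copy(), self.name.copy(),
                         self.residue_number.copy(), self.residue_name.copy(),
                         self.chain.copy(), self.coords.copy(),
                         self.vdw_radius.copy(), dict(self.subunit_roles),
                         self.title)

    # -- selection ----------------------------------------------------------

    def mask(self, chain: str | Iterable[str] | None = None,
             residue_number: int | None = None,
             atom_name: str | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            m &= np.isin(self.chain, chains)
        if residue_number is not None:
            m &= self.residue_number == residue_number
        if atom_name is not None:
            m &= self.name == atom_name
        return m

    def residue_indices(self, site: ResidueSelector) -> np.ndarray:
        idx = np.flatnonzero(self.mask(chain=site.chain,
                                       residue_number=site.residue_number))
        if idx.size == 0:
            raise SiteError(f"no residue {site} in structure")
        return idx

    def atom_index(self, site: ResidueSelector, atom_name: str) -> int:
        idx = self.residue_indices(site)
        sel = idx[self.name[idx] == atom_name]
        if sel.size == 0:
            raise SiteError(f"residue {site} has no atom {atom_name}")
        return int(sel[0])

    def subset(self, mask: np.ndarray, title: str = "") -> "Structure":
        roles = {c: r for c, r in self.subunit_roles.items()
                 if c in set(self.chain[mask])}
        return Structure(self.element[mask], self.name[mask],
                         self.residue_number[mask], self.residue_name[mask],
                         self.chain[mask], self.coords[mask],
                         self.vdw_radius[mask], roles,
                         title or self.title)

    # -- rigid transforms ---------------------------------------------------

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    center: np.ndarray | None = None) -> "Structure":
        """Apply ``x -> R (x - c) + c + t``; returns a new Structure."""
        out = self.copy()
        xyz = out.coords
        if rotation is not None:
            c = np.zeros(3) if center is None else np.asarray(center, float)
            xyz = (xyz - c) @ np.asarray(rotation, float).T + c
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        out.coords = xyz
        return out

    def centroid(self, mask: np.ndarray | None = None,
                 mass_weighted: bool = False) -> np.ndarray:
        xyz = self.coords if mask is None else self.coords[mask]
        if xyz.size == 0:
            raise ValueError("empty selection has no centroid")
        if mass_weighted:
            el = self.element if mask is None else self.element[mask]
            w = np.array([ATOMIC_MASS.get(e, 12.011) for e in el])
            return (xyz * w[:, None]).sum(0) / w.sum()
        return xyz.mean(0)


# -- PDB I/O ---------------------------------------------------------------


def _validate_pdb_text(text: str) -> None:
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fragment = line[lo:hi]
            try:
                float(fragment)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: non-numeric {what} coordinate field "
                    f"{fragment.strip()!r}") from None
    if n_atoms == 0:
        raise PDBParseError("no ATOM/HETATM records in input")


def read_structure(text: str, radii: Mapping[str, float] = VDW_RADII,
                   subunit_roles: Mapping[str, str] | None = None) -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Only the first model is kept; altloc '' and 'A' are retained.  Van der
    Waals radii are assigned per element from ``radii`` (default table:
    C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 A).
    """
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    element, name, resnum, resname, chain, xyz = [], [], [], [], [], []
    model = st[0]
    for ch in model:
        for res in ch:
            for atom in res:
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                element.append(atom.element.name)
                name.append(atom.name)
                resnum.append(res.seqid.num)
                resname.append(res.name)
                chain.append(ch.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    vdw = np.array([radii.get(e, DEFAULT_VDW) for e in element])
    return Structure(np.array(element), np.array(name),
                     np.array(resnum, dtype=int), np.array(resname),
                     np.array(chain), np.array(xyz, dtype=float), vdw,
                     dict(subunit_roles or {}), st.name or "")


def write_structure(structure: Structure) -> str:
    """Serialise a Structure back to PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.title
    model = gemmi.Model("1")
    current_chain = None
    chain_obj = None
    res_key = None
    res_obj = None
    for i in range(len(structure)):
        cname = str(structure.chain[i])
        if cname != current_chain:
            chain_obj = gemmi.Chain(cname)
            model.add_chain(chain_obj)
            chain_obj = model[len(model) - 1]
            current_chain = cname
            res_key = None
        key = (cname, int(structure.residue_number[i]))
        if key != res_key:
            res = gemmi.Residue()
            res.name = str(structure.residue_name[i])
            res.seqid = gemmi.SeqId(int(structure.residue_number[i]), " ")
            chain_obj.add_residue(res)
            res_obj = chain_obj[len(chain_obj) - 1]
            res_key = key
        atom = gemmi.Atom()
        atom.name = str(structure.name[i])
        atom.element = gemmi.Element(str(structure.element[i]))
        x, y, z = structure.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        res_obj.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# -- cysteine modelling ----------------------------------------------------


def place_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom D from internal coordinates relative to chain A-B-C.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``dihedral_deg``
    the A-B-C-D torsion (IUPAC sign convention).
    """
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("colinear A-B-C reference atoms")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        -bond * np.sin(theta) * np.cos(phi),
                        -bond * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def mutate_to_cys(structure: Structure, site: ResidueSelector,
                  chi1: float = SG_CHI1) -> Structure:
    """Model a cysteine at ``site`` by single-atom SG placement.

    The side chain beyond CB is removed and one SG atom is placed at the
    ideal geometry (CB-SG 1.81 A, CA-CB-SG 114 deg) with the chi1 torsion at
    the modal cysteine rotamer (-65 deg by default).  The residue is renamed
    CYS.  The input structure is not modified.  Glycine (no CB) is not a
    supported target.
    """
    idx = structure.residue_indices(site)
    names = structure.name[idx]
    pos = {}
    for ref in ("N", "CA", "CB"):
        where = idx[names == ref]
        if where.size == 0:
            kind = "unsupported-site: glycine has no CB" if ref == "CB" else \
                f"missing backbone atom {ref}"
            raise SiteError(f"residue {site}: {kind}")
        pos[ref] = structure.coords[where[0]]
    if not np.any(names == "C"):
        raise SiteError(f"residue {site}: missing backbone atom C")

    sg_xyz = place_internal(pos["N"], pos["CA"], pos["CB"], SG_BOND, SG_ANGLE, chi1)

    keep = np.ones(len(structure), dtype=bool)
    sidechain = ~np.isin(names, BACKBONE + ("CB",))
    keep[idx[sidechain]] = False
    out = structure.subset(keep)
    # rename residue and append SG right after its CB
    ridx = out.residue_indices(site)
    out.residue_name[ridx] = "CYS"
    insert_at = int(ridx[-1]) + 1

    def ins(arr, value):
        return np.insert(arr, insert_at, value)

    return Structure(ins(out.element, "S"), ins(out.name, "SG"),
                     ins(out.residue_number, site.residue_number),
                     ins(out.residue_name, "CYS"), ins(out.chain, site.chain),
                     np.insert(out.coords, insert_at, sg_xyz, axis=0),
                     ins(out.vdw_radius, VDW_RADII["S"]),
                     dict(out.subunit_roles), out.title)


def sg_distance(structure: Structure, a: ResidueSelector,
                b: ResidueSelector) -> float:
    """Euclidean distance (A) between the SG atoms of two cysteines."""
    for sel in (a, b):
        ridx = structure.residue_indices(sel)
        if not np.all(structure.residue_name[ridx] == "CYS"):
            raise SiteError(f"residue {sel} is not a cysteine")
    ia = structure.atom_index(a, "SG")
    ib = structure.atom_index(b, "SG")
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))


# -- group geometry --------------------------------------------------------


def _group_masks(structure: Structure, group1: Sequence[str],
                 group2: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    g1, g2 = set(group1), set(group2)
    if not g1 or not g2:
        raise ValueError("chain groups must be non-empty")
    if g1 & g2:
        raise ValueError(f"overlapping chain groups: {sorted(g1 & g2)}")
    m1 = structure.mask(chain=g1)
    m2 = structure.mask(chain=g2)
    if not m1.any() or not m2.any():
        raise ValueError("chain group selects no atoms")
    return m1, m2


def com_separation(structure: Structure, group1: Sequence[str],
                   group2: Sequence[str], mass_weighted: bool = False) -> float:
    """Distance (A) between the centroids of two disjoint chain groups.

    Centroids are unweighted over atoms by default; set ``mass_weighted`` for
    true centres of mass.  At the ~1 A reporting scale of dimer separations
    the two agree.
    """
    m1, m2 = _group_masks(structure, group1, group2)
    c1 = structure.centroid(m1, mass_weighted)
    c2 = structure.centroid(m2, mass_weighted)
    return float(np.linalg.norm(c1 - c2))


# -- solvent accessibility (Shrake-Rupley) ---------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (deterministic golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(structure: Structure, targets: np.ndarray | None = None,
         probe_radius: float = PROBE_RADIUS, n_points: int = 1024) -> np.ndarray:
    """Shrake-Rupley accessible surface area per target atom (A^2).

    For each target atom, a deterministic quasi-uniform point set is placed
    on the sphere of radius ``r_vdw + probe``; the accessible area is the
    fraction of points outside every neighbour's inflated sphere times the
    full sphere area.  ``targets`` is a boolean mask or integer index array
    over atoms (default: all atoms).

    Exact for an isolated atom: 4*pi*(r+probe)^2.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    if targets is None:
        target_idx = np.arange(len(structure))
    else:
        targets = np.asarray(targets)
        target_idx = (np.flatnonzero(targets) if targets.dtype == bool
                      else targets.astype(int))
    sphere = fibonacci_sphere(n_points)
    radii = structure.vdw_radius + probe_radius
    tree = cKDTree(structure.coords)
    max_r = radii.max()
    out = np.empty(len(target_idx))
    for k, i in enumerate(target_idx):
        ri = radii[i]
        center = structure.coords[i]
        neigh = tree.query_ball_point(center, ri + max_r)
        neigh = [j for j in neigh if j != i]
        pts = center + ri * sphere
        if neigh:
            nxyz = structure.coords[neigh]
            nr = radii[list(neigh)]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(-1)
            buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[k] = frac * 4.0 * np.pi * ri ** 2
    return out


# -- clash counting --------------------------------------------------------


def count_clashes(structure: Structure, group1: Sequence[str],
                  group2: Sequence[str], cutoff: float = 2.2) -> int:
    """Number of inter-group atom pairs closer than ``cutoff`` (strict <).

    Uses a KD-tree for candidate pairs but the count equals the exact
    all-pairs answer; pairs at exactly the cutoff do not count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    m1, m2 = _group_masks(structure, group1, group2)
    xyz1 = structure.coords[m1]
    xyz2 = structure.coords[m2]
    t1 = cKDTree(xyz1)
    t2 = cKDTree(xyz2)
    pairs = t1.query_ball_tree(t2, cutoff)
    count = 0
    for i, js in enumerate(pairs):
        if js:
            d = np.linalg.norm(xyz2[js] - xyz1[i], axis=1)
            count += int((d < cutoff).sum())
    return count


def distance_report(structure: Structure,
                    pairs: Sequence[tuple[ResidueSelector, ResidueSelector]]):
    """CSV-ready table of SG-SG distances for selector pairs."""
    import pandas as pd
    rows = []
    for a, b in pairs:
        rows.append({"structure": structure.title, "site_a": str(a),
                     "site_b": str(b),
                     "sg_sg_angstrom": sg_distance(structure, a, b)})
    return pd.DataFrame(rows)
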