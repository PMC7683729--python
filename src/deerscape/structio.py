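"""Protein structure I/O and geometric primitives.

Structures are held as flat sequences of atom records in author numbering,
with coordinates in Angstrom (the PDB native unit).  All public distance-type
measurements are reported in nanometres, matching the convention used for
inter-spin and inter-domain distances throughout the package.

The residue-numbering convention of the study proteins differs from the
deposited PDB files (the reconstructed-ancestor alignment drops N-terminal
tags); :func:`renumber` applies the per-entry shift and records it so a
double application is caught.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "SiteRef",
    "PDBParseError",
    "NUMBERING_OFFSETS",
    "parse_pdb",
    "parse_pdb_models",
    "write_pdb",
    "renumber",
    "ca_distance",
    "radius_of_gyration",
    "measure_dihedral",
    "place_atom_nerf",
    "superpose",
]

#: paper-minus-PDB residue numbering shifts for the study's deposited entries
NUMBERING_OFFSETS = {
    "3KBR": -25,
    "5HPQ": -11,
    "6BQE": -11,
    "5T0W": -11,
    "5TUJ": -11,
    "5JOS": -11,
    "6WUP": -11,
}

ANGSTROM_PER_NM = 10.0


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records (carries the line number)."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray  # (3,) float, Angstrom
    hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.atom_name}: xyz must be 3 finite components")
        object.__setattr__(self, "xyz", xyz)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class SiteRef:
    """A residue addressed by chain and residue number (paper numbering)."""

    chain_id: str
    res_seq: int

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_seq}"


@dataclass
class Structure:
    atoms: list[AtomRecord]
    provenance: str = ""
    numbering_offset_applied: int | None = None

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.provenance!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coordinates(self, selection: Callable[[AtomRecord], bool] | None = None) -> np.ndarray:
        atoms = self.atoms if selection is None else [a for a in self.atoms if selection(a)]
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.xyz for a in atoms])

    def residue_atoms(self, site: SiteRef) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == site.chain_id and a.res_seq == site.res_seq]

    def atom(self, site: SiteRef, atom_name: str) -> AtomRecord:
        for a in self.residue_atoms(site):
            if a.atom_name == atom_name:
                return a
        raise KeyError(f"no atom {atom_name!r} at site {site} in {self.provenance!r}")

    def ca(self, site: SiteRef) -> np.ndarray:
        try:
            return self.atom(site, "CA").xyz
        except KeyError:
            raise KeyError(f"site {site} has no CA atom in {self.provenance!r}") from None

    def with_atoms(self, atoms: Iterable[AtomRecord]) -> "Structure":
        return Structure(list(atoms), self.provenance, self.numbering_offset_applied)


# --------------------------------------------------------------------------
# PDB fixed-column reading / writing
# --------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than coordinate columns")
    try:
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21]
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    if icode:
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported "
            "(the study's structures use plain sequential numbering)"
        )
    if not element:
        # fall back on the leading letter of the atom name (columns 13-14)
        element = "".join(c for c in line[12:14] if c.isalpha()) or atom_name[:1]
    return AtomRecord(
        atom_name=atom_name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        xyz=np.array([x, y, z]),
        hetero=line.startswith("HETATM"),
        occupancy=occupancy,
        altloc=altloc,
    )


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one altloc per (chain, residue, atom name): highest occupancy,
    first seen on a tie."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.res_seq, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [replace(best[k], altloc="") for k in order]


def parse_pdb_models(text: str, provenance: str = "") -> list[Structure]:
    """Parse every MODEL block of a PDB character stream.

    A file without MODEL records yields a single structure.  Alternate
    locations are collapsed to the highest-occupancy conformer (first on a
    tie); insertion codes are rejected.
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current or not saw_model:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no ATOM/HETATM records found (empty structure)")
    return [
        Structure(_dedupe_altlocs(m), provenance=provenance or f"model {i + 1}")
        for i, m in enumerate(models)
    ]


def parse_pdb(text: str, provenance: str = "", model: int = 1) -> Structure:
    """Parse a PDB character stream, returning one model (the first by
    default)."""
    models = parse_pdb_models(text, provenance=provenance)
    if not 1 <= model <= len(models):
        raise PDBParseError(f"model {model} requested but file has {len(models)}")
    return models[model - 1]


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = a.atom_name
    # column-13 convention: 1-2 char element names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 and len(a.element) < 2 else f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field} {a.res_name:>3s} {a.chain_id}"
        f"{a.res_seq:>4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(structures: Structure | Sequence[Structure]) -> str:
    """Serialize one structure (or a model series) as PDB fixed-column text."""
    if isinstance(structures, Structure):
        lines = [_format_atom_line(a, i + 1) for i, a in enumerate(structures.atoms)]
        lines.append("END")
        return "\n".join(lines) + "\n"
    lines = []
    for m, s in enumerate(structures, start=1):
        lines.append(f"MODEL {m:>8d}")
        lines.extend(_format_atom_line(a, i + 1) for i, a in enumerate(s.atoms))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Numbering convention
# --------------------------------------------------------------------------

def renumber(s: Structure, offset: int | None = None, pdb_id: str | None = None) -> Structure:
    """Shift every residue number by the paper-minus-PDB offset.

    Either an explicit ``offset`` or a known ``pdb_id`` (looked up in
    :data:`NUMBERING_OFFSETS`) must be given.  Re-applying to an already
    renumbered structure raises.
    """
    if s.numbering_offset_applied is not None:
        raise ValueError(
            f"structure {s.provenance!r} already renumbered "
            f"(offset {s.numbering_offset_applied} applied)"
        )
    if offset is None:
        if pdb_id is None:
            raise ValueError("provide an explicit offset or a known PDB id")
        try:
            offset = NUMBERING_OFFSETS[pdb_id.upper()]
        except KeyError:
            raise ValueError(
                f"no numbering offset on record for PDB id {pdb_id!r}; pass offset explicitly"
            ) from None
    atoms = [replace(a, res_seq=a.res_seq + offset) for a in s.atoms]
    return Structure(atoms, provenance=s.provenance, numbering_offset_applied=offset)


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def ca_distance(s: Structure, a: SiteRef, b: SiteRef) -> float:
    """Euclidean Calpha-Calpha distance between two sites, in nm."""
    return float(np.linalg.norm(s.ca(a) - s.ca(b))) / ANGSTROM_PER_NM


def default_heavy(a: AtomRecord) -> bool:
    return not a.is_hydrogen


def radius_of_gyration(
    s: Structure, selection: Callable[[AtomRecord], bool] = default_heavy
) -> float:
    """Mass-unweighted radius of gyration of the selected atoms, in nm.

    Rg = sqrt(mean ||x_i - xbar||^2) over the selection (non-hydrogen atoms
    by default).
    """
    coords = s.coordinates(selection)
    if coords.shape[0] == 0:
        raise ValueError("radius_of_gyration: empty atom selection")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1)))) / ANGSTROM_PER_NM


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention,
    in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * np.linalg.norm(b1) * nb2:
        raise ValueError("measure_dihedral: p1, p2, p3 are collinear")
    if np.linalg.norm(n2) < 1e-10 * nb2 * np.linalg.norm(b3):
        raise ValueError("measure_dihedral: p2, p3, p4 are collinear")
    angle = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def place_atom_nerf(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point from internal coordinates (natural-extension
    reference frame).

    The new point is at ``bond`` Angstrom from ``p3``, forms the given bond
    angle (degrees) at ``p3``, and the torsion p1-p2-p3-new equals ``torsion``
    degrees.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    if not 0.0 < angle < 180.0:
        raise ValueError("place_atom_nerf: bond angle must lie in (0, 180) degrees")
    if bond <= 0:
        raise ValueError("place_atom_nerf: bond length must be positive")
    bc = p3 - p2
    nbc = np.linalg.norm(bc)
    if nbc < 1e-10:
        raise ValueError("place_atom_nerf: degenerate frame (p2 == p3)")
    bc = bc / nbc
    ab = p2 - p1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("place_atom_nerf: degenerate frame (p1, p2, p3 collinear)")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose: coordinate arrays must share shape (n, 3)")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, trans, rmsd
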