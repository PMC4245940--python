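"""Per-nucleotide geometry of a nucleosome core particle.

From a PDB coordinate file this module derives the quantities used to
rationalise rotational-position effects on photoproduct formation and
deamination:

* the superhelix (disc) axis of the wrapped DNA, estimated from the
  phosphorus atoms;
* the orientation angle of each pyrimidine base relative to the local
  outward radial direction (a proxy for the perpendicular to the histone
  core surface);
* per-nucleotide mean crystallographic B-factors (flexibility proxy);
* the geometry of adjacent pyrimidine pairs relevant to photodimer
  formation: distance between the C5-C6 bond midpoints and the
  C5(i)-C6(i)-C6(j)-C5(j) improper torsion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "NucleosomeStructure",
    "SuperhelixAxis",
    "BaseOrientation",
    "PhotodimerGeometry",
    "PdbParseError",
    "MissingAtomError",
    "parse_structure",
    "estimate_superhelix_axis",
    "base_orientation_angle",
    "mean_temperature_factor",
    "photodimer_geometry",
    "dihedral_angle",
]

PYRIMIDINE_RESNAMES = {"DC", "DT", "DU", "C", "T", "U", "5CM", "5MC", "CYT", "THY", "URA"}
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DI", "DU", "5CM", "5MC", "A", "C", "G", "T", "U"}
WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}
RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


class PdbParseError(ValueError):
    """A coordinate record could not be parsed; the message names the line."""


class MissingAtomError(KeyError):
    """A residue lacks an atom required by the requested operation."""


@dataclass(frozen=True)
class Atom:
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    x: float
    y: float
    z: float
    b_factor: float
    occupancy: float
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class NucleosomeStructure:
    """Parsed atoms plus a DNA/protein classification of the chains."""

    atoms: pd.DataFrame
    dna_chains: frozenset[str]
    protein_chains: frozenset[str]

    @classmethod
    def from_atoms(cls, atoms: Iterable[Atom]) -> "NucleosomeStructure":
        df = pd.DataFrame(
            [
                {
                    "name": a.name,
                    "residue_name": a.residue_name,
                    "residue_number": a.residue_number,
                    "chain_id": a.chain_id,
                    "x": a.x,
                    "y": a.y,
                    "z": a.z,
                    "b_factor": a.b_factor,
                    "occupancy": a.occupancy,
                    "altloc": a.altloc,
                }
                for a in atoms
            ]
        )
        if df.empty:
            raise ValueError("no atoms")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        by_chain = df.groupby("chain_id")["residue_name"]
        dna, protein = set(), set()
        for chain, resnames in by_chain:
            frac_dna = resnames.isin(DNA_RESNAMES).mean()
            (dna if frac_dna >= 0.5 else protein).add(chain)
        return cls(df, frozenset(dna), frozenset(protein))

    def residue(self, chain_id: str, residue_number: int) -> pd.DataFrame:
        sel = self.atoms[
            (self.atoms.chain_id == chain_id)
            & (self.atoms.residue_number == residue_number)
        ]
        if sel.empty:
            raise KeyError(f"residue {chain_id}/{residue_number} not found")
        return sel

    def atom_coord(self, chain_id: str, residue_number: int, atom_name: str) -> np.ndarray:
        res = self.residue(chain_id, residue_number)
        sel = res[res.name == atom_name]
        if sel.empty:
            raise MissingAtomError(
                f"residue {chain_id}/{residue_number} "
                f"({res.residue_name.iloc[0]}) lacks atom {atom_name}"
            )
        return sel[["x", "y", "z"]].iloc[0].to_numpy(dtype=float)

    def residue_name(self, chain_id: str, residue_number: int) -> str:
        return self.residue(chain_id, residue_number).residue_name.iloc[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NucleosomeStructure":
        """Rigid-body copy: ``x -> R x + t`` (used by invariance tests)."""
        df = self.atoms.copy()
        xyz = df[["x", "y", "z"]].to_numpy() @ np.asarray(rotation).T + np.asarray(translation)
        df[["x", "y", "z"]] = xyz
        return NucleosomeStructure(df, self.dna_chains, self.protein_chains)


@dataclass(frozen=True)
class SuperhelixAxis:
    """Line through ``origin`` with unit ``direction`` (the disc normal)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", d)

    def radial_vector(self, point: np.ndarray) -> np.ndarray:
        """Component of ``point - origin`` perpendicular to the axis."""
        rel = np.asarray(point, dtype=float) - self.origin
        return rel - np.dot(rel, self.direction) * self.direction


@dataclass(frozen=True)
class BaseOrientation:
    chain_id: str
    residue_number: int
    residue_name: str
    angle_deg: float
    radial_distance_A: float


@dataclass(frozen=True)
class PhotodimerGeometry:
    chain_id: str
    residue_i: int
    residue_j: int
    interbond_distance_A: float
    improper_torsion_deg: float


def _validate_coordinate_fields(pdb_text: str) -> None:
    # gemmi is forgiving about malformed numbers; pre-check so errors name
    # the offending line.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PdbParseError(
                        f"line {lineno}: non-numeric {what} coordinate {fieldtxt!r}"
                    ) from None


def parse_structure(pdb_text: str) -> NucleosomeStructure:
    """Parse PDB-format text into a :class:`NucleosomeStructure`.

    Waters are dropped.  Where a residue carries alternate locations the
    highest-occupancy conformer is kept (ties broken by file order).
    """
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(str(exc)) from exc
    if len(st) == 0:
        raise PdbParseError("no models in PDB input")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.name.strip() in WATER_RESNAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        name=atom.name,
                        residue_name=residue.name.strip(),
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        b_factor=atom.b_iso,
                        occupancy=atom.occ,
                        altloc=atom.altloc if atom.altloc != "\0" else "",
                    )
                )
    if not atoms:
        raise PdbParseError("no non-water atoms parsed")
    return NucleosomeStructure.from_atoms(atoms)


def estimate_superhelix_axis(
    structure: NucleosomeStructure, min_p_atoms: int = 10
) -> SuperhelixAxis:
    """Disc normal of the wrapped DNA from its phosphorus atoms.

    The DNA superhelix is a flat spiral, so the phosphorus cloud is
    pancake-shaped: its normal is the eigenvector of the smallest
    eigenvalue of the coordinate covariance.  The sign is fixed to point
    along +z of the lab frame (ties toward +x) so repeated runs agree.
    """
    dna = structure.atoms[structure.atoms.chain_id.isin(structure.dna_chains)]
    p = dna[dna.name == "P"][["x", "y", "z"]].to_numpy(dtype=float)
    if len(p) < min_p_atoms:
        raise ValueError(f"need >= {min_p_atoms} DNA phosphorus atoms, found {len(p)}")
    centroid = p.mean(axis=0)
    cov = np.cov((p - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0.9 * evals[1]:
        raise ValueError("degenerate (near-spherical) phosphorus cloud; no unique axis")
    direction = evecs[:, 0]
    if abs(direction[2]) > 1e-12:
        if direction[2] < 0:
            direction = -direction
    elif direction[0] < 0:
        direction = -direction
    return SuperhelixAxis(origin=centroid, direction=direction / np.linalg.norm(direction))


def _ring_atoms(structure: NucleosomeStructure, chain_id: str, residue_number: int):
    name = structure.residue_name(chain_id, residue_number)
    if name not in PYRIMIDINE_RESNAMES:
        raise ValueError(
            f"residue {chain_id}/{residue_number} ({name}) is not a pyrimidine"
        )
    return {a: structure.atom_coord(chain_id, residue_number, a) for a in RING_ATOMS}


def base_orientation_angle(
    structure: NucleosomeStructure,
    chain_id: str,
    residue_number: int,
    axis: SuperhelixAxis,
) -> BaseOrientation:
    """Angle between the base's bisecting vector and the outward radial.

    The bisecting vector runs from the midpoint of the C6-N1 bond to the
    midpoint of the N3-C4 bond, crossing the pyrimidine ring toward its
    major-groove (C4) edge.  The "perpendicular to the histone surface"
    is realised as the radial unit vector from the superhelix axis to the
    ring centroid: 0 deg means the base points straight out from the
    histone core, 180 deg straight in.
    """
    ring = _ring_atoms(structure, chain_id, residue_number)
    mid_start = 0.5 * (ring["C6"] + ring["N1"])
    mid_end = 0.5 * (ring["N3"] + ring["C4"])
    bisect = mid_end - mid_start
    centroid = np.mean(list(ring.values()), axis=0)
    radial = axis.radial_vector(centroid)
    r_norm = np.linalg.norm(radial)
    b_norm = np.linalg.norm(bisect)
    if r_norm <= 1e-9 or b_norm <= 1e-9:
        raise ValueError("degenerate geometry: zero-length radial or bisecting vector")
    cosang = np.clip(np.dot(bisect, radial) / (b_norm * r_norm), -1.0, 1.0)
    return BaseOrientation(
        chain_id=chain_id,
        residue_number=residue_number,
        residue_name=structure.residue_name(chain_id, residue_number),
        angle_deg=math.degrees(math.acos(cosang)),
        radial_distance_A=float(r_norm),
    )


def mean_temperature_factor(
    structure: NucleosomeStructure, chain_id: str, residue_number: int
) -> float:
    """Unweighted mean B-factor over all atoms of the nucleotide."""
    res = structure.residue(chain_id, residue_number)
    return float(res.b_factor.mean())


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral of four points in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    # sign follows the IUPAC convention used by biotite/MDAnalysis
    ang = math.degrees(math.atan2(-y, x))
    return 180.0 if np.isclose(ang, -180.0) else ang


def photodimer_geometry(
    structure: NucleosomeStructure,
    chain_id: str,
    residue_i: int,
    residue_j: int,
) -> PhotodimerGeometry:
    """Geometry of the two C5=C6 bonds that fuse in a cyclobutane dimer.

    ``residue_j`` must be the 3' neighbour of ``residue_i`` on the same
    strand.  Returns the distance between the bond midpoints and the
    C5(i)-C6(i)-C6(j)-C5(j) improper torsion (0 deg for perfectly
    eclipsed stacked bonds).
    """
    if residue_j != residue_i + 1:
        raise ValueError(
            f"residues {residue_i} and {residue_j} are not sequential on chain {chain_id}"
        )
    for resno in (residue_i, residue_j):
        name = structure.residue_name(chain_id, resno)
        if name not in PYRIMIDINE_RESNAMES:
            raise ValueError(f"residue {chain_id}/{resno} ({name}) is not a pyrimidine")
    c5_i = structure.atom_coord(chain_id, residue_i, "C5")
    c6_i = structure.atom_coord(chain_id, residue_i, "C6")
    c5_j = structure.atom_coord(chain_id, residue_j, "C5")
    c6_j = structure.atom_coord(chain_id, residue_j, "C6")
    mid_i = 0.5 * (c5_i + c6_i)
    mid_j = 0.5 * (c5_j + c6_j)
    return PhotodimerGeometry(
        chain_id=chain_id,
        residue_i=residue_i,
        residue_j=residue_j,
        interbond_distance_A=float(np.linalg.norm(mid_i - mid_j)),
        improper_torsion_deg=dihedral_angle(c5_i, c6_i, c6_j, c5_j),
    )
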