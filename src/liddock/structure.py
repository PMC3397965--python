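"""Molecular structure model: atoms, residues, topology, PDB I/O, superposition.

Coordinates are in Angstroms throughout. Residue numbering follows the author
(PDB) numbering, 1-based, with inclusive ranges. Altloc policy: blank or 'A'
kept, others dropped. Hydrogens are optional everywhere; analyses that need
them document a heavy-atom fallback.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import RigidTransform, dihedral_angle, kabsch, rotation_about_axis

HBOND_CLASSES = ("donor", "acceptor", "both", "nonpolar")

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "X": 12.0,
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "SEP", "ACE",
}


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class ClassificationError(ValueError):
    """Raised when atoms cannot be assigned a hydrogen-bond class."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty or mismatched."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    epsilon: float = 0.05      # LJ well depth, kcal/mol
    sigma: float = 3.2         # LJ zero-crossing distance, Angstrom
    hbond_class: str | None = None
    residue_ref: int = -1
    mass: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.mass is None:
            self.mass = _ELEMENT_MASS.get(self.element, 12.0)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""


@dataclass(frozen=True)
class Torsion:
    """Proper torsion a-b-c-d over global atom indices.

    Energy form (documented in docs/methods.md):
        E(phi) = 0.5 * barrier * (1 - cos(periodicity * (phi - phase)))
    which is zero at phi = phase and has height `barrier`.
    """

    a: int
    b: int
    c: int
    d: int
    rotatable: bool = False
    barrier: float = 2.0       # kcal/mol
    periodicity: int = 3
    phase: float = np.pi       # radians


@dataclass(frozen=True)
class HarmonicBond:
    """Quadratic bond term E = 0.5 * k * (r - r0)**2 (k in kcal/mol/A^2)."""

    i: int
    j: int
    k: float
    r0: float


@dataclass(frozen=True)
class SegmentSpec:
    chain_id: str
    first_seq_id: int
    last_seq_id: int

    def __post_init__(self) -> None:
        if self.first_seq_id > self.last_seq_id:
            raise ValueError("segment first_seq_id must be <= last_seq_id")


class Structure:
    """A molecule: residues with atoms, plus bonded topology.

    Topology (bonds, torsions, harmonic terms) is populated by the synthetic
    generators; structures read from PDB carry coordinates and names only,
    which is sufficient for every nonbonded analysis.
    """

    def __init__(self, residues: list[Residue] | None = None,
                 bonds: list[tuple[int, int]] | None = None,
                 torsions: list[Torsion] | None = None,
                 harmonic_bonds: list[HarmonicBond] | None = None,
                 metadata: dict | None = None) -> None:
        self.residues: list[Residue] = residues or []
        self.bonds: list[tuple[int, int]] = [tuple(b) for b in (bonds or [])]
        self.torsions: list[Torsion] = list(torsions or [])
        self.harmonic_bonds: list[HarmonicBond] = list(harmonic_bonds or [])
        self.metadata: dict = dict(metadata or {})
        self._reindex()
        self._validate_topology()

    # -- bookkeeping -------------------------------------------------------

    def _reindex(self) -> None:
        i = 0
        for ri, res in enumerate(self.residues):
            for atom in res.atoms:
                atom.residue_ref = ri
                i += 1
        self._n_atoms = i

    def _validate_topology(self) -> None:
        n = self.n_atoms
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
        for t in self.torsions:
            for idx in (t.a, t.b, t.c, t.d):
                if not 0 <= idx < n:
                    raise ValueError("torsion references a missing atom")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def get_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = self.atoms
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(atoms, coords):
            a.coords = c.copy()

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def atom_index(self, seq_id: int, atom_name: str,
                   chain_id: str | None = None) -> int:
        idx = 0
        for res in self.residues:
            for atom in res.atoms:
                if (res.seq_id == seq_id and atom.name == atom_name
                        and (chain_id is None or res.chain_id == chain_id)):
                    return idx
                idx += 1
        raise SelectionError(f"no atom {atom_name} in residue {seq_id}")

    def select(self, atom_names: set[str] | None = None,
               heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms matching a name filter (None = all)."""
        out = []
        for i, atom in enumerate(self.atoms):
            if atom_names is not None and atom.name not in atom_names:
                continue
            if heavy_only and not atom.is_heavy:
                continue
            out.append(i)
        return np.array(out, dtype=int)

    # -- torsion machinery -------------------------------------------------

    def _adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def downstream_atoms(self, b: int, c: int) -> list[int]:
        """Atoms on the c-side of bond b-c (excluding c's path back through b)."""
        adj = self._adjacency()
        seen = {b, c}
        stack = [c]
        out = []
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    out.append(nb)
                    stack.append(nb)
        return out

    def rotatable_torsions(self) -> list[Torsion]:
        return [t for t in self.torsions if t.rotatable]

    def get_torsion_angles(self) -> np.ndarray:
        coords = self.get_coords()
        return np.array([
            dihedral_angle(coords[t.a], coords[t.b], coords[t.c], coords[t.d])
            for t in self.rotatable_torsions()
        ])


def apply_torsions(structure: Structure, angles: np.ndarray,
                   coords: np.ndarray | None = None) -> np.ndarray:
    """Return coordinates with the rotatable torsions set to `angles` (radians).

    Bond lengths and bond angles are untouched: each torsion rotation moves
    only the atoms downstream of its central bond, about that bond's axis.
    """
    torsions = structure.rotatable_torsions()
    if len(angles) != len(torsions):
        raise ValueError(f"expected {len(torsions)} torsion angles, got {len(angles)}")
    out = np.array(structure.get_coords() if coords is None else coords, dtype=float)
    for t, target in zip(torsions, angles):
        current = dihedral_angle(out[t.a], out[t.b], out[t.c], out[t.d])
        delta = float(target) - current
        if abs(delta) < 1e-15:
            continue
        # rotating the downstream atoms by +x about the b->c axis decreases
        # the measured dihedral by x under the IUPAC sign convention
        axis = out[t.c] - out[t.b]
        rot = rotation_about_axis(axis, -delta)
        moving = structure.downstream_atoms(t.b, t.c)
        out[moving] = (out[moving] - out[t.c]) @ rot.T + out[t.c]
    return out


# -- PDB I/O ---------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, int, str, np.ndarray, str, str]:
    name = line[12:16].strip()
    altloc = line[16:17]
    resname = line[17:20].strip() or line[17:21].strip()
    chain = line[21:22].strip() or "A"
    try:
        seq_id = int(line[22:26])
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: malformed residue number") from exc
    icode = line[26:27].strip()
    try:
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: malformed coordinate field") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1] if name[:1].isalpha() else name[1:2]
        if name[:1].isdigit():
            element = "H"
        elif name.startswith(("H", "1H", "2H", "3H")):
            element = "H"
    return name, altloc, resname, seq_id, icode, xyz, element.upper(), chain


def read_pdb(path: str | Path, model: int | None = None) -> Structure:
    """Read a PDB file into a Structure (first MODEL unless `model` given).

    Author residue numbering and insertion codes are preserved; altloc blank
    or 'A' kept. Raises :class:`PDBFormatError` on malformed or atom-free
    files, OSError on unreadable paths.
    """
    structures = read_pdb_models(path)
    want = 0 if model is None else model
    if want >= len(structures):
        raise PDBFormatError(f"model index {want} out of range ({len(structures)} models)")
    return structures[want]


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a (possibly multi-model) PDB file."""
    path = Path(path)
    text = path.read_text()
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append((lineno, line))
    if current or not models:
        models.append(current)
    out = []
    for lines in models:
        if not lines and saw_model_record:
            continue
        out.append(_build_structure(lines, source=str(path)))
    if not out or all(s.n_atoms == 0 for s in out):
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    return out


def _build_structure(lines, source: str) -> Structure:
    residues: list[Residue] = []
    key_to_res: dict[tuple, Residue] = {}
    for lineno, line in lines:
        name, altloc, resname, seq_id, icode, xyz, element, chain = \
            _parse_atom_line(line, lineno)
        if altloc not in (" ", "", "A"):
            continue
        key = (chain, seq_id, icode)
        res = key_to_res.get(key)
        if res is None:
            res = Residue(resname, seq_id, chain, [], icode)
            key_to_res[key] = res
            residues.append(res)
        res.atoms.append(Atom(name=name, element=element, coords=xyz))
    return Structure(residues, metadata={"source": source})


def write_pdb(structure: Structure, path: str | Path,
              models: list[np.ndarray] | None = None) -> None:
    """Write a Structure (or an ensemble of coordinate frames) as PDB."""
    path = Path(path)
    frames = models if models is not None else [structure.get_coords()]
    multi = len(frames) > 1
    lines: list[str] = []
    for mi, coords in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        atoms = structure.atoms
        for atom, xyz in zip(atoms, np.asarray(coords, float)):
            res = structure.residues[atom.residue_ref]
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            record = "ATOM  " if res.name in STANDARD_RESIDUES else "HETATM"
            lines.append(
                f"{record}{serial:5d} {name:<4s} {res.name:<3s} {res.chain_id:1s}"
                f"{res.seq_id:4d}{res.icode or ' ':1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# -- atom classification ---------------------------------------------------

def _load_class_table() -> dict:
    with resources.files("liddock.data").joinpath("atom_classes.yaml").open() as fh:
        return yaml.safe_load(fh)


_CLASS_TABLE: dict | None = None


def assign_atom_classes(structure: Structure, strict: bool = False) -> Structure:
    """Assign every atom one hydrogen-bond class (donor/acceptor/both/nonpolar).

    Deterministic lookup on (residue name, atom name) with element fallback.
    Idempotent. With ``strict=True`` unknown residue/atom names raise a
    :class:`ClassificationError` listing the offenders; by default they warn
    and fall back to the element rule (nonpolar if the element is unknown).
    """
    global _CLASS_TABLE
    if _CLASS_TABLE is None:
        _CLASS_TABLE = _load_class_table()
    table = _CLASS_TABLE
    offenders = []
    for res in structure.residues:
        res_rules = table["residues"].get(res.name, {})
        known_res = res.name in STANDARD_RESIDUES or res.name in table["residues"]
        for atom in res.atoms:
            cls = res_rules.get(atom.name)
            if cls is None:
                cls = table["backbone"].get(atom.name)
            if cls is None:
                cls = table["elements"].get(atom.element)
            if not known_res or cls is None:
                offenders.append(f"{res.name}{res.seq_id}:{atom.name}")
                cls = cls or "nonpolar"
            atom.hbond_class = cls
    if offenders:
        msg = "unknown residue/atom names: " + ", ".join(sorted(set(offenders)))
        if strict:
            raise ClassificationError(msg)
        warnings.warn(msg + " (defaulted by element rule)", stacklevel=2)
    return structure


# -- segment extraction and superposition ----------------------------------

def extract_segment(structure: Structure, spec: SegmentSpec) -> Structure:
    """Deep-copied sub-structure of the residues in `spec` (inclusive range).

    Topology is restricted to bonds/torsions internal to the segment. Raises
    a SelectionError when any residue in the range is absent.
    """
    wanted = [r for r in structure.residues
              if r.chain_id == spec.chain_id
              and spec.first_seq_id <= r.seq_id <= spec.last_seq_id]
    present = {r.seq_id for r in wanted}
    missing = [s for s in range(spec.first_seq_id, spec.last_seq_id + 1)
               if s not in present]
    if missing:
        raise SelectionError(
            f"residues missing from chain {spec.chain_id}: {missing}")
    # map old global atom indices -> new
    old_index: dict[int, int] = {}
    idx = 0
    keep = set(id(r) for r in wanted)
    for res in structure.residues:
        for _ in res.atoms:
            if id(res) in keep:
                old_index[idx] = len(old_index)
            idx += 1
    new_res = [_copy.deepcopy(r) for r in wanted]
    remap = old_index
    bonds = [(remap[i], remap[j]) for i, j in structure.bonds
             if i in remap and j in remap]
    torsions = [Torsion(remap[t.a], remap[t.b], remap[t.c], remap[t.d],
                        t.rotatable, t.barrier, t.periodicity, t.phase)
                for t in structure.torsions
                if all(k in remap for k in (t.a, t.b, t.c, t.d))]
    harm = [HarmonicBond(remap[h.i], remap[h.j], h.k, h.r0)
            for h in structure.harmonic_bonds if h.i in remap and h.j in remap]
    return Structure(new_res, bonds, torsions, harm,
                     metadata=dict(structure.metadata))


def superpose(mobile: Structure, reference: Structure,
              atom_names: set[str] | None = None) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of `mobile` onto `reference`.

    Atoms are paired positionally after applying the name filter to both
    structures; a SelectionError is raised for empty or unequal selections.
    """
    mi = mobile.select(atom_names)
    ri = reference.select(atom_names)
    if len(mi) == 0 or len(ri) == 0:
        raise SelectionError("empty superposition selection")
    if len(mi) != len(ri):
        raise SelectionError(f"selection size mismatch: {len(mi)} vs {len(ri)}")
    return kabsch(mobile.get_coords()[mi], reference.get_coords()[ri])
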