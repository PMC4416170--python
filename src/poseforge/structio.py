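"""Structure I/O: receptors, ligand poses, and pose sets.

Everything downstream works on a deliberately small heavy-atom coordinate
model: an element symbol plus a 3-vector in Å per atom. Hydrogens are
dropped on input (decoy RMSDs in the docking literature are heavy-atom),
waters and non-standard HET records are excluded from receptors by default,
and atom order is preserved because pose RMSD pairs atoms by index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MoleculeStructure",
    "PoseSet",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "PairingError",
    "read_receptor",
    "read_poses",
    "write_sdf",
    "assemble_pose_set",
]


class StructureError(ValueError):
    """Base class for structure I/O and validation failures."""


class FormatError(StructureError):
    """A file did not parse as the named format."""


class EmptyStructureError(StructureError):
    """No heavy atoms survived parsing/filtering."""


class PairingError(StructureError):
    """Two poses cannot be paired atom-by-atom."""


# Standard amino-acid residues kept when reading a receptor; everything else
# in HETATM records (waters, ions, co-crystallised ligands) is excluded by
# default because ligand poses are supplied separately.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL "
    "MSE SEC PYL".split()
)

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element symbol (uppercase), coordinates in Å, role flag."""

    element: str
    coords: tuple[float, float, float]
    is_ligand: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError("AtomRecord requires a non-empty element symbol")
        if not all(np.isfinite(c) for c in self.coords):
            raise StructureError(f"non-finite coordinates {self.coords!r}")


@dataclass
class MoleculeStructure:
    """An ordered heavy-atom point set. Atom order is significant (RMSD pairing)."""

    molecule_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.molecule_id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=np.float64)

    def with_coords(self, xyz: np.ndarray, molecule_id: str | None = None) -> "MoleculeStructure":
        """Copy of this structure with replaced coordinates (same elements/order)."""
        xyz = np.asarray(xyz, dtype=np.float64)
        if xyz.shape != (len(self.atoms), 3):
            raise PairingError(
                f"coordinate array shape {xyz.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [
            AtomRecord(a.element, (float(x), float(y), float(z)), a.is_ligand)
            for a, (x, y, z) in zip(self.atoms, xyz)
        ]
        return MoleculeStructure(molecule_id or self.molecule_id, atoms)


@dataclass
class PoseSet:
    """A native ligand pose plus candidate poses for one receptor.

    ``rmsd_to_native`` is the heavy-atom RMSD of each candidate to the native
    pose in the shared receptor frame; ``energies`` are per-candidate scores
    (arbitrary units, lower = more favorable) used for decoy representative
    selection.
    """

    complex_id: str
    receptor: MoleculeStructure
    native: MoleculeStructure
    candidates: list[MoleculeStructure]
    energies: np.ndarray | None = None
    rmsd_to_native: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.native)
        for i, cand in enumerate(self.candidates):
            if len(cand) != n:
                raise PairingError(
                    f"candidate {i} of {self.complex_id!r} has {len(cand)} atoms, native has {n}"
                )
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=np.float64)
            if self.energies.shape != (len(self.candidates),):
                raise StructureError("energies must have one value per candidate")
        if self.rmsd_to_native is not None:
            self.rmsd_to_native = np.asarray(self.rmsd_to_native, dtype=np.float64)
            if self.rmsd_to_native.shape != (len(self.candidates),):
                raise StructureError("rmsd_to_native must have one value per candidate")
            if np.any(self.rmsd_to_native < 0):
                raise StructureError("rmsd_to_native must be non-negative")


# ---------------------------------------------------------------------------
# element handling

_TWO_LETTER = frozenset(
    {"BR", "CL", "FE", "ZN", "MG", "MN", "CA", "NA", "SE", "CU", "NI", "CO", "CD", "HG", "SI"}
)


def _normalize_element(raw: str) -> str:
    sym = raw.strip().upper()
    # mol2 SYBYL atom types look like "C.3", "N.ar", "O.co2"
    if "." in sym:
        sym = sym.split(".", 1)[0]
    return sym


def _is_hydrogen(element: str) -> bool:
    return element in ("H", "D", "T")


# ---------------------------------------------------------------------------
# PDB receptor reading


def read_receptor(
    path: str | Path,
    fmt: str = "pdb",
    *,
    keep_hetero: bool = False,
) -> MoleculeStructure:
    """Read a receptor structure, returning heavy atoms only.

    Waters are always excluded. HETATM records whose residue is not a
    standard amino acid are excluded unless ``keep_hetero`` is set (ligands
    are expected in separate MOL2/SDF files).
    """
    path = Path(path)
    if fmt.lower() != "pdb":
        raise FormatError(f"unsupported receptor format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            resname = line[17:20].strip().upper()
            if resname in _WATER_NAMES:
                continue
            if rec == "HETATM" and resname not in STANDARD_RESIDUES and not keep_hetero:
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path.name}:{lineno}: bad coordinate field: {line.rstrip()!r}") from exc
            element = _normalize_element(line[76:78]) if len(line) >= 78 and line[76:78].strip() else ""
            if not element:
                # fall back on the atom-name column (first alphabetic character)
                name = line[12:16].strip()
                element = next((c for c in name if c.isalpha()), "").upper()
            if not element:
                raise FormatError(f"{path.name}:{lineno}: cannot determine element")
            if _is_hydrogen(element):
                continue
            atoms.append(AtomRecord(element, (x, y, z), is_ligand=False))
    if not atoms:
        raise EmptyStructureError(f"{path.name}: no heavy atoms after filtering")
    return MoleculeStructure(path.stem, atoms)


# ---------------------------------------------------------------------------
# ligand pose reading (multi-record SDF / MOL2)


def read_poses(path: str | Path, fmt: str | None = None) -> list[MoleculeStructure]:
    """Read a multi-record ligand file into one structure per record.

    Input order is preserved; heavy atoms only. Records whose heavy-atom
    count differs from the first record trigger a consistency warning (they
    are still returned — the caller decides).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "sdf"
    fmt = fmt.lower()
    if fmt in ("sdf", "sd", "mol"):
        mols = _read_sdf(path)
    elif fmt == "mol2":
        mols = _read_mol2(path)
    else:
        raise FormatError(f"unsupported pose format {fmt!r}")
    if not mols:
        raise EmptyStructureError(f"{path.name}: no molecules parsed")
    counts = [len(m) for m in mols]
    bad = [i for i, c in enumerate(counts) if c != counts[0]]
    if bad:
        warnings.warn(
            f"{path.name}: records {[i + 1 for i in bad]} have heavy-atom counts "
            f"{[counts[i] for i in bad]} differing from record 1 ({counts[0]})",
            stacklevel=2,
        )
    return mols


def _read_sdf(path: Path) -> list[MoleculeStructure]:
    from rdkit import Chem

    mols: list[MoleculeStructure] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"{path.name}: record {i + 1} failed to parse as SDF")
        conf = mol.GetConformer()
        atoms: list[AtomRecord] = []
        for atom in mol.GetAtoms():
            element = atom.GetSymbol().upper()
            if _is_hydrogen(element):
                continue
            p = conf.GetAtomPosition(atom.GetIdx())
            atoms.append(AtomRecord(element, (p.x, p.y, p.z), is_ligand=True))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"pose_{i + 1}"
        if not atoms:
            raise EmptyStructureError(f"{path.name}: record {i + 1} has no heavy atoms")
        mols.append(MoleculeStructure(name, atoms))
    return mols


def _read_mol2(path: Path) -> list[MoleculeStructure]:
    # TRIPOS mol2; only @<TRIPOS>MOLECULE and @<TRIPOS>ATOM sections are
    # needed for the heavy-atom coordinate model.
    mols: list[MoleculeStructure] = []
    name: str | None = None
    in_atoms = False
    pending_name = False
    atoms: list[AtomRecord] = []

    def flush() -> None:
        nonlocal atoms, name
        if name is not None:
            if not atoms:
                raise EmptyStructureError(f"{path.name}: molecule {name!r} has no heavy atoms")
            mols.append(MoleculeStructure(name, atoms))
        atoms = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                section = stripped[len("@<TRIPOS>"):].upper()
                if section == "MOLECULE":
                    flush()
                    name = None
                    pending_name = True
                    in_atoms = False
                else:
                    in_atoms = section == "ATOM"
                    pending_name = False
                continue
            if pending_name and stripped:
                name = stripped or f"pose_{len(mols) + 1}"
                pending_name = False
                continue
            if in_atoms and stripped:
                parts = stripped.split()
                if len(parts) < 6:
                    raise FormatError(f"{path.name}:{lineno}: malformed ATOM line {stripped!r}")
                try:
                    x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: bad coordinate in {stripped!r}") from exc
                element = _normalize_element(parts[5])
                if _is_hydrogen(element):
                    continue
                atoms.append(AtomRecord(element, (x, y, z), is_ligand=True))
    flush()
    return mols


def write_sdf(structures: Iterable[MoleculeStructure], path: str | Path) -> None:
    """Write structures as a bond-less V2000 SD file (element + coordinates only)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    path = Path(path)
    with Chem.SDWriter(str(path)) as writer:
        for struct in structures:
            rw = Chem.RWMol()
            for atom in struct.atoms:
                a = Chem.Atom(atom.element.capitalize())
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            conf = Chem.Conformer(len(struct))
            for i, atom in enumerate(struct.atoms):
                conf.SetAtomPosition(i, Point3D(*atom.coords))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", struct.molecule_id)
            writer.write(mol)


# ---------------------------------------------------------------------------
# pose-set assembly


def assemble_pose_set(
    receptor: MoleculeStructure,
    native: MoleculeStructure,
    candidates: Sequence[MoleculeStructure],
    energies: Sequence[float] | None = None,
    complex_id: str | None = None,
) -> PoseSet:
    """Bundle receptor + native + candidates, computing RMSD-to-native for each."""
    from .posemetrics import rmsd

    n = len(native)
    for i, cand in enumerate(candidates):
        if len(cand) != n:
            raise PairingError(
                f"candidate {i} ({cand.molecule_id!r}) has {len(cand)} atoms; native has {n}"
            )
    rmsds = np.array([rmsd(native, c) for c in candidates], dtype=np.float64)
    return PoseSet(
        complex_id=complex_id or receptor.molecule_id,
        receptor=receptor,
        native=native,
        candidates=list(candidates),
        energies=None if energies is None else np.asarray(energies, dtype=np.float64),
        rmsd_to_native=rmsds,
    )
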