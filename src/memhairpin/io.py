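"""Core data model and I/O for labelled structures and trajectories.

Internal units are nm for lengths and ns for times everywhere; readers
convert at the boundary (PDB Å → nm, GRO native nm).  Atoms carry a
coarse group label (protein / membrane / solvent / other) assigned from
the residue name, so that downstream contact analysis can select
"protein heavy atoms" and "membrane heavy atoms" without re-deriving
chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Structure",
    "Trajectory",
    "FragmentSpec",
    "ParseError",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "infer_element",
    "assign_group",
]


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


#: residue names mapped to the membrane group (extendable by callers)
MEMBRANE_RESNAMES = frozenset(
    {"POPC", "POPG", "DOPC", "DOPG", "DPPC", "DPPG", "DMPC", "DMPG", "LIP"}
)

#: residue names mapped to the solvent group (waters and common ions)
SOLVENT_RESNAMES = frozenset(
    {"SOL", "WAT", "HOH", "TIP3", "TIP4", "SPC", "K", "CL", "NA", "POT",
     "CLA", "SOD", "ION", "KCL"}
)

#: two-letter element symbols recognised by the name-based inference
TWO_LETTER_ELEMENTS = frozenset({"CL", "NA", "MG", "FE", "ZN", "BR", "CA2"})


def infer_element(atom_name: str, overrides: dict[str, str] | None = None) -> str:
    """Infer an element symbol from an atom name.

    Digits are stripped and the first alphabetic character is used;
    ``overrides`` maps full atom names to element symbols for the
    two-letter cases (e.g. ``{"CLA": "Cl"}``).
    """
    if overrides and atom_name in overrides:
        return overrides[atom_name]
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


def assign_group(residue_name: str,
                 membrane_resnames: frozenset[str] = MEMBRANE_RESNAMES,
                 solvent_resnames: frozenset[str] = SOLVENT_RESNAMES) -> str:
    name = residue_name.upper()
    if name in membrane_resnames:
        return "membrane"
    if name in solvent_resnames:
        return "solvent"
    return "protein"


@dataclass(frozen=True)
class Atom:
    """One atom with its residue bookkeeping and coarse group label."""

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    group: str = "protein"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Frame:
    """One trajectory frame: a time stamp, coordinates in nm, optional box."""

    time: float
    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray | None = None  # orthorhombic (3,) nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths (nm)")


@dataclass
class Structure:
    """A static set of atoms with one coordinate set (nm) and optional box."""

    atoms: list[Atom]
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def frame(self) -> Frame:
        return Frame(time=0.0, coordinates=self.coordinates, box=self.box)


_TIME_TOL = 1e-9


@dataclass
class Trajectory:
    """A time-ordered sequence of frames over a fixed atom table.

    ``dt`` is the uniform frame spacing in ns; ``condition`` is a free
    label usually carrying the PG mole fraction of the membrane.
    """

    atoms: list[Atom]
    frames: list[Frame]
    replica_id: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} coordinates for {n} atoms"
                )
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array (nm)."""
        return np.stack([f.coordinates for f in self.frames])

    @property
    def dt(self) -> float:
        """Uniform frame spacing in ns (median spacing with a warning if ragged)."""
        times = self.times
        if len(times) < 2:
            raise ValueError("dt undefined for a trajectory with <2 frames")
        spacings = np.diff(times)
        dt = float(np.median(spacings))
        if np.any(np.abs(spacings - dt) > max(_TIME_TOL, 1e-6 * dt)):
            warnings.warn(
                "non-uniform frame spacing; using the median as dt", stacklevel=2
            )
        return dt


@dataclass(frozen=True)
class FragmentSpec:
    """Residue bookkeeping for the analysed helical-hairpin fragment.

    Defaults describe the α1-3 hairpin: author residues 26–156, with the
    mobile C-terminal tail 152–156 excluded from PCA and Trp71 tracked
    for per-residue SASA.
    """

    first_residue: int = 26
    last_residue: int = 156
    pca_last_residue: int = 151
    trp_residue: int = 71

    def __post_init__(self) -> None:
        if not (self.first_residue <= self.pca_last_residue <= self.last_residue):
            raise ValueError("require first ≤ pca_last ≤ last residue")

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1

    @property
    def residues(self) -> np.ndarray:
        return np.arange(self.first_residue, self.last_residue + 1)

    @property
    def pca_residues(self) -> np.ndarray:
        return np.arange(self.first_residue, self.pca_last_residue + 1)


# ---------------------------------------------------------------------------
# structure readers (PDB / GRO via MDAnalysis, with pre-validation)
# ---------------------------------------------------------------------------

def _validate_pdb(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}: truncated ATOM/HETATM record at line {lineno}"
                    )
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: bad coordinate field at line {lineno}"
                    ) from exc


def _validate_gro(path: Path) -> None:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: GRO file too short")
    try:
        natoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}: bad atom count at line 2") from exc
    if len(lines) < natoms + 3:
        raise ParseError(f"{path}: expected {natoms} atom lines, file truncated")
    for lineno in range(3, natoms + 3):
        if len(lines[lineno - 1].rstrip("\n")) < 44:
            raise ParseError(f"{path}: truncated atom record at line {lineno}")


def read_structure(path: str | Path, format: str | None = None,
                   element_overrides: dict[str, str] | None = None,
                   ) -> tuple[list[Atom], Frame]:
    """Read a single-model PDB or GRO file into (atoms, frame), in nm.

    The format is taken from the extension unless given explicitly.
    Elements are inferred from atom names when the file carries no
    element column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "gro"}:
        raise ValueError(f"unknown structure format {fmt!r} (expected pdb or gro)")
    if fmt == "pdb":
        _validate_pdb(path)
    else:
        _validate_gro(path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:  # pragma: no cover - MDA internal failures
            raise ParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    for i, a in enumerate(u.atoms):
        try:
            element = a.element if a.element else infer_element(a.name, element_overrides)
        except (mda.exceptions.NoDataError, AttributeError):
            element = infer_element(a.name, element_overrides)
        resname = str(a.resname)
        atoms.append(Atom(
            index=i, name=str(a.name), element=element.capitalize(),
            residue_index=int(a.resid), residue_name=resname,
            group=assign_group(resname),
        ))
    coords = u.atoms.positions.astype(float) / 10.0  # Å → nm (MDA is Å for both)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = u.dimensions[:3].astype(float) / 10.0
    return atoms, Frame(time=0.0, coordinates=coords, box=box)


# ---------------------------------------------------------------------------
# internal plain-text trajectory format
# ---------------------------------------------------------------------------
#
# Header:   "# memhairpin-traj 1", "replica <id>", "condition <label>",
#           "natoms <n>" followed by one atom row per atom
#           (index name element resid resname group).
# Body:     per frame, "frame <time_ns> [bx by bz]" then n coordinate rows.

_FMT_MAGIC = "# memhairpin-traj 1"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the internal plain-text trajectory format (round-trips to 1e-6 nm)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_FMT_MAGIC + "\n")
        fh.write(f"replica {traj.replica_id}\n")
        fh.write(f"condition {traj.condition}\n")
        fh.write(f"natoms {len(traj.atoms)}\n")
        for a in traj.atoms:
            fh.write(f"{a.index} {a.name} {a.element} {a.residue_index} "
                     f"{a.residue_name} {a.group}\n")
        for f in traj.frames:
            if f.box is not None:
                fh.write(f"frame {f.time:.9f} {f.box[0]:.9f} {f.box[1]:.9f} "
                         f"{f.box[2]:.9f}\n")
            else:
                fh.write(f"frame {f.time:.9f}\n")
            np.savetxt(fh, f.coordinates, fmt="%.7f")


def _read_internal(path: Path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _FMT_MAGIC:
        raise ParseError(f"{path}: not an internal trajectory file (bad magic)")
    try:
        replica_id = int(lines[1].split()[1])
        condition = lines[2].split(maxsplit=1)[1] if len(lines[2].split()) > 1 else ""
        natoms = int(lines[3].split()[1])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed header") from exc
    atoms: list[Atom] = []
    for lineno in range(4, 4 + natoms):
        parts = lines[lineno].split()
        if len(parts) != 6:
            raise ParseError(f"{path}: malformed atom row at line {lineno + 1}")
        atoms.append(Atom(index=int(parts[0]), name=parts[1], element=parts[2],
                          residue_index=int(parts[3]), residue_name=parts[4],
                          group=parts[5]))
    frames: list[Frame] = []
    i = 4 + natoms
    while i < len(lines):
        if not lines[i].startswith("frame"):
            raise ParseError(f"{path}: expected frame header at line {i + 1}")
        parts = lines[i].split()
        time = float(parts[1])
        box = np.array(parts[2:5], dtype=float) if len(parts) >= 5 else None
        block = lines[i + 1:i + 1 + natoms]
        if len(block) < natoms:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        coords = np.array([row.split() for row in block], dtype=float)
        frames.append(Frame(time=time, coordinates=coords, box=box))
        i += 1 + natoms
    return Trajectory(atoms=atoms, frames=frames, replica_id=replica_id,
                      condition=condition)


def read_trajectory(topology: str | Path | None,
                    traj: str | Path | Sequence[str | Path]) -> Trajectory:
    """Read one or more internal-format trajectory files, concatenated in order.

    ``topology`` may be a PDB/GRO file whose atom table replaces the one
    stored in the trajectory files; pass ``None`` to use the stored table.
    Frame times must come out strictly increasing across the concatenation.
    """
    paths = [Path(traj)] if isinstance(traj, (str, Path)) else [Path(p) for p in traj]
    parts = [_read_internal(p) for p in paths]
    atoms = parts[0].atoms
    if topology is not None:
        top_atoms, _ = read_structure(topology)
        if len(top_atoms) != len(atoms):
            raise ValueError(
                f"topology has {len(top_atoms)} atoms, trajectory has {len(atoms)}"
            )
        atoms = top_atoms
    frames: list[Frame] = []
    for part in parts:
        if len(part.atoms) != len(atoms):
            raise ValueError("atom count differs between trajectory files")
        frames.extend(part.frames)
    out = Trajectory(atoms=atoms, frames=frames,
                     replica_id=parts[0].replica_id, condition=parts[0].condition)
    out.dt  # noqa: B018 - trigger the non-uniform-spacing warning eagerly
    return out


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = ("N", "CA", "C", "O")


def select_atoms(atoms: Sequence[Atom], selector, *,
                 include_backbone_h: bool = False) -> np.ndarray:
    """Select atom indices by a named selector.

    Selectors: ``"protein_heavy"``, ``"membrane_heavy"``, ``"backbone"``,
    ``("residue_range", first, last)``, ``("residue", i)``.  Selections
    compose by intersection (``np.intersect1d``) since each returns a
    sorted index array.  An empty result warns but is not an error.
    """
    if selector == "protein_heavy":
        mask = [a.group == "protein" and a.is_heavy for a in atoms]
    elif selector == "membrane_heavy":
        mask = [a.group == "membrane" and a.is_heavy for a in atoms]
    elif selector == "backbone":
        names = _BACKBONE_NAMES + (("H",) if include_backbone_h else ())
        mask = [a.group == "protein" and a.name in names for a in atoms]
    elif isinstance(selector, tuple) and selector[0] == "residue_range":
        _, first, last = selector
        if first > last:
            raise ValueError(f"bad residue range {first}–{last}")
        mask = [first <= a.residue_index <= last for a in atoms]
    elif isinstance(selector, tuple) and selector[0] == "residue":
        mask = [a.residue_index == selector[1] for a in atoms]
    else:
        raise ValueError(f"unknown selector {selector!r}")
    idx = np.flatnonzero(np.asarray(mask))
    if idx.size == 0:
        warnings.warn(f"selector {selector!r} matched no atoms", stacklevel=2)
    return idx
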