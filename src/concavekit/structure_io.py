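"""Reading, writing and selecting macromolecular structures.

Structures are flattened into a list of :class:`AtomRecord` grouped by chain,
with the element-level annotations (heavy, polar, van der Waals radius) that
the solvent-accessibility and interface-geometry computations downstream
consume.  Parsing of PDB and mmCIF files is delegated to gemmi; only the
first model of multi-model files is used, and alternate locations are
resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "StructureError",
    "StructureFormatError",
    "EmptyStructureError",
    "SelectionError",
    "VDW_RADII",
    "read_structure",
    "select_atoms",
    "write_pdb",
    "model_from_atoms",
]


class StructureError(Exception):
    """Base class for structure-handling failures."""


class StructureFormatError(StructureError):
    """File could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """Parsed structure contains no heavy atoms."""


class SelectionError(StructureError):
    """An atom selection referenced chains absent from the model."""


# Chothia-style radii as distributed with NACCESS (Hubbard & Thornton 1993);
# element-level fallbacks for anything the table does not name.  Values in A.
VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "H": 1.00,
    "D": 1.00,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.47,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 1.74,
    "MN": 1.61,
    "NA": 2.27,
    "K": 2.75,
}
DEFAULT_VDW_RADIUS = 1.80

POLAR_ELEMENTS = frozenset({"N", "O"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with the annotations interface analysis needs.

    ``is_polar`` follows the element-level convention used for buried-area
    splits: nitrogen and oxygen are polar, carbon and sulfur are not.
    Residue numbers are taken verbatim from the source file.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    is_heavy: bool
    is_polar: bool
    vdw_radius: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(
                f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector"
            )
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.serial}: vdw_radius must be positive")
        if self.is_polar and not self.is_heavy:
            raise StructureError(f"atom {self.serial}: polar atoms must be heavy")


@dataclass
class StructureModel:
    """Ordered atom list grouped into chains.

    ``chains`` maps each chain id to the half-open ``(start, stop)`` index
    range of its atoms; atoms of one chain are contiguous and every atom
    belongs to exactly one chain.
    """

    atoms: list[AtomRecord]
    chains: dict[str, tuple[int, int]]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """(chain, residue_number, residue_name) in atom order, deduplicated."""
        seen: list[tuple[str, int, str]] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_number, a.residue_name)
            if not seen or seen[-1] != key:
                seen.append(key)
        return seen

    def sequence(self, chain_id: str) -> str:
        return "".join(
            THREE_TO_ONE.get(name, "X") for _, _, name in self.residues(chain_id)
        )

    def subset(self, chains: Iterable[str]) -> "StructureModel":
        atoms = select_atoms(self, set(chains), heavy_only=False)
        return model_from_atoms(atoms, source_id=self.source_id)


def _element_annotations(
    element: str, overrides: Mapping[str, float] | None
) -> tuple[bool, bool, float]:
    el = element.upper()
    is_heavy = el not in ("H", "D")
    radius = None
    if overrides:
        radius = overrides.get(el)
    if radius is None:
        radius = VDW_RADII.get(el, DEFAULT_VDW_RADIUS)
    return is_heavy, is_heavy and el in POLAR_ELEMENTS, radius


def model_from_atoms(atoms: Sequence[AtomRecord], source_id: str = "") -> StructureModel:
    """Build a model from atoms, grouping contiguous runs of one chain id."""
    chains: dict[str, tuple[int, int]] = {}
    out: list[AtomRecord] = []
    order = []
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        if a.chain_id not in by_chain:
            order.append(a.chain_id)
            by_chain[a.chain_id] = []
        by_chain[a.chain_id].append(a)
    pos = 0
    for cid in order:
        group = by_chain[cid]
        chains[cid] = (pos, pos + len(group))
        out.extend(group)
        pos += len(group)
    return StructureModel(atoms=out, chains=chains, source_id=source_id)


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
    keep_hetero: bool = False,
    vdw_overrides: Mapping[str, float] | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by file order).  Waters and
    non-polymer heteroatoms are excluded unless the corresponding flag is
    set.  Hydrogens are retained but flagged ``is_heavy = False``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise ValueError(f"format must be one of {sorted(fmt_map)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            if residue.is_water() and not keep_waters:
                continue
            is_het = residue.het_flag == "H" and not residue.is_water()
            if is_het and not keep_hetero:
                continue
            # resolve altlocs: keep the highest-occupancy copy of each atom name
            best: dict[str, gemmi.Atom] = {}
            name_order: list[str] = []
            for atom in residue:
                if atom.name not in best:
                    best[atom.name] = atom
                    name_order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in name_order:
                atom = best[name]
                el = atom.element.name.upper()
                is_heavy, is_polar, radius = _element_annotations(el, vdw_overrides)
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=el,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_heavy=is_heavy,
                        is_polar=is_polar,
                        vdw_radius=radius,
                    )
                )
    if not any(a.is_heavy for a in atoms):
        raise EmptyStructureError(f"{path}: structure contains no heavy atoms")
    return model_from_atoms(atoms, source_id=path.stem)


def select_atoms(
    model: StructureModel,
    chains: set[str] | None = None,
    heavy_only: bool = False,
    names: set[str] | None = None,
) -> list[AtomRecord]:
    """Order-preserving subset by chain, heaviness and atom name."""
    if chains is not None:
        missing = set(chains) - set(model.chains)
        if missing:
            raise SelectionError(
                f"unknown chain(s) {sorted(missing)}; available: {sorted(model.chains)}"
            )
    out = []
    for a in model.atoms:
        if chains is not None and a.chain_id not in chains:
            continue
        if heavy_only and not a.is_heavy:
            continue
        if names is not None and a.name not in names:
            continue
        out.append(a)
    return out


def _pdb_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 letter names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-width PDB v3.3 ATOM records (coordinates to 3 decimals)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {_pdb_atom_name(a.name, a.element)}"
            f" {a.residue_name:<3s} {a.chain_id[:1]}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    prev_chain = None
    out_lines = []
    for line, a in zip(lines, model.atoms):
        if prev_chain is not None and a.chain_id != prev_chain:
            out_lines.append("TER")
        out_lines.append(line)
        prev_chain = a.chain_id
    out_lines.append("TER")
    out_lines.append("END")
    Path(path).write_text("\n".join(out_lines) + "\n")
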