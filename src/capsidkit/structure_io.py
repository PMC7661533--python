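"""Reading, writing and selecting atomic models.

Supports the fixed-column PDB dialect and the mmCIF ``atom_site`` loop
(tokenised through :mod:`biotite`'s CIF engine).  Coordinates are Ångström
throughout the package; unit conversion to nm happens only in the
reporting layer.

Conventions
-----------
* Residue numbering is taken verbatim from the file (author numbering);
  ranges are 1-based and inclusive.
* When alternate locations are present, only the highest-occupancy
  conformer of each atom is kept, so every atom has one position.
* Waters are excluded by default (``include_waters=True`` to keep them).
* Strict PDB output refuses >99,999 atoms or multi-character chain ids;
  use mmCIF for expanded capsids.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "BiomtOperator",
    "StructureModel",
    "StructureError",
    "StructureParseError",
    "StructureWriteError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "atoms_coords",
]

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(Exception):
    """Base class for structure I/O failures."""


class StructureParseError(StructureError):
    """A file could not be interpreted in the declared format."""


class StructureWriteError(StructureError):
    """A model cannot be represented in the requested output dialect."""


@dataclass(frozen=True)
class Atom:
    """One atomic coordinate record.

    ``position`` is a length-3 float array in Å.  ``res_seq`` may be
    negative (author numbering is kept verbatim).
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetatm: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        object.__setattr__(self, "position", pos)

    def moved_to(self, position: np.ndarray) -> "Atom":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class BiomtOperator:
    """A rigid-body operator: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("operator needs a 3x3 rotation and a 3-vector")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def is_proper_rotation(self, tol: float = 1e-6) -> bool:
        rot = self.rotation
        return (
            np.allclose(rot @ rot.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(rot) - 1.0) < tol
        )


@dataclass
class StructureModel:
    """An ordered atom collection plus optional assembly operators."""

    atoms: list[Atom] = field(default_factory=list)
    source_format: str = "memory"
    biomt_operators: Optional[list[BiomtOperator]] = None

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3), dtype=float)
        return np.stack([a.position for a in self.atoms])

    def validate(self, tol: float = 1e-6) -> None:
        chains = set(self.chains)
        for atom in self.atoms:
            if atom.chain_id not in chains:  # pragma: no cover - tautology guard
                raise StructureError(f"atom {atom.serial} has unlisted chain")
        if self.biomt_operators:
            for i, op in enumerate(self.biomt_operators):
                if not op.is_proper_rotation():
                    raise StructureError(
                        f"assembly operator {i + 1} is not a proper rotation"
                    )


def atoms_coords(atoms: Sequence[Atom]) -> np.ndarray:
    """Stack atom positions into an (N, 3) array."""
    if not atoms:
        return np.empty((0, 3), dtype=float)
    return np.stack([a.position for a in atoms])


# ---------------------------------------------------------------------------
# Reading


def read_structure(
    path: str | os.PathLike,
    format: str = "auto",
    include_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is ``pdb``, ``mmcif`` or ``auto`` (by extension, falling
    back to content sniffing).  All ATOM/HETATM records with coordinates
    are returned in file order; assembly operators (REMARK 350 BIOMT or
    ``_pdbx_struct_oper_list``) are captured when present.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "pdb":
        model = _read_pdb(path)
    else:
        model = _read_mmcif(path)
    if not include_waters:
        model.atoms = [a for a in model.atoms if a.res_name not in _WATER_RES]
    model.atoms = _collapse_altlocs(model.atoms)
    return model


def _resolve_format(path: str, format: str) -> str:
    if format in ("pdb", "mmcif"):
        return format
    if format != "auto":
        raise ValueError(f"unknown format {format!r}; use 'pdb', 'mmcif' or 'auto'")
    # sniff content rather than trusting the extension: the auto writer may
    # fall back to mmCIF for oversized models regardless of suffix
    with open(path) as handle:
        head = handle.read(8192)
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    if any(head.startswith(tag) or f"\n{tag}" in head for tag in ("ATOM", "HETATM", "HEADER", "REMARK", "CRYST1", "MODEL")):
        return "pdb"
    ext = os.path.splitext(path)[1].lower()
    return "mmcif" if ext in (".cif", ".mmcif") else "pdb"


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    # Atoms tagged with altloc are pre-merged at parse time; this pass
    # removes exact duplicates of (chain, res_seq, name) keeping the
    # higher-occupancy record, which also makes re-reads idempotent.
    best: dict[tuple, int] = {}
    order: list[int] = []
    for idx, atom in enumerate(atoms):
        key = (atom.chain_id, atom.res_seq, atom.res_name, atom.name)
        if key in best:
            if atom.occupancy > atoms[best[key]].occupancy:
                order[order.index(best[key])] = idx
                best[key] = idx
        else:
            best[key] = idx
            order.append(idx)
    if len(order) == len(atoms):
        return atoms
    return [atoms[i] for i in order]


def _read_pdb(path: str) -> StructureModel:
    atoms: list[Atom] = []
    biomt_rows: dict[int, dict[int, tuple[list[float], float]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record in ("ATOM  ", "HETATM"):
                try:
                    atoms.append(_parse_pdb_atom_line(line))
                except (ValueError, IndexError) as exc:
                    raise StructureParseError(
                        f"{path}: malformed coordinate record at line {lineno}: {exc}"
                    ) from exc
            elif line.startswith("REMARK 350") and "BIOMT" in line:
                try:
                    _accumulate_biomt(line, biomt_rows)
                except (ValueError, IndexError) as exc:
                    raise StructureParseError(
                        f"{path}: malformed BIOMT record at line {lineno}"
                    ) from exc
    operators = _assemble_biomt(biomt_rows) if biomt_rows else None
    return StructureModel(atoms=atoms, source_format="pdb", biomt_operators=operators)


def _parse_pdb_atom_line(line: str) -> Atom:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise ValueError("record shorter than coordinate fields")
    serial = int(line[6:11])
    name = line[12:16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    res_seq = int(line[22:26])
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    b_factor = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    return Atom(
        serial=serial,
        name=name,
        element=element.capitalize(),
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        position=np.array([x, y, z]),
        occupancy=occupancy,
        b_factor=b_factor,
        hetatm=line.startswith("HETATM"),
    )


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "SE", "NA", "MN"):
        return stripped[:2]
    return stripped[:1] if stripped else "C"


def _accumulate_biomt(
    line: str, rows: dict[int, dict[int, tuple[list[float], float]]]
) -> None:
    fields = line.split()
    # REMARK 350 BIOMT<row> <opnum> m1 m2 m3 t
    tag = fields[2]
    row = int(tag[-1])
    opnum = int(fields[3])
    values = [float(v) for v in fields[4:8]]
    rows.setdefault(opnum, {})[row] = (values[:3], values[3])


def _assemble_biomt(
    rows: dict[int, dict[int, tuple[list[float], float]]]
) -> list[BiomtOperator]:
    operators = []
    for opnum in sorted(rows):
        triplet = rows[opnum]
        if set(triplet) != {1, 2, 3}:
            raise StructureParseError(f"BIOMT operator {opnum} is incomplete")
        rot = np.array([triplet[r][0] for r in (1, 2, 3)])
        trans = np.array([triplet[r][1] for r in (1, 2, 3)])
        operators.append(BiomtOperator(rotation=rot, translation=trans))
    return operators


def _read_mmcif(path: str) -> StructureModel:
    import biotite.structure.io.pdbx as pdbx

    try:
        cif = pdbx.CIFFile.read(path)
        block = cif.block
    except Exception as exc:
        raise StructureParseError(f"{path}: not parseable as mmCIF: {exc}") from exc
    if "atom_site" not in block:
        raise StructureParseError(f"{path}: mmCIF file has no atom_site loop")
    site = block["atom_site"]

    def col(name: str, dtype, default=None):
        if name in site:
            return site[name].as_array(dtype)
        if default is None:
            raise StructureParseError(f"{path}: atom_site missing _{name}")
        return None

    n = len(site["Cartn_x"].as_array(float))
    group = col("group_PDB", str, default="")
    group = group if group is not None else np.full(n, "ATOM")
    serial = col("id", str, default="")
    name = col("label_atom_id", str)
    element = col("type_symbol", str, default="")
    res_name = col("label_comp_id", str)
    chain = None
    if "auth_asym_id" in site:
        chain = site["auth_asym_id"].as_array(str)
    else:
        chain = site["label_asym_id"].as_array(str)
    if "auth_seq_id" in site:
        res_seq = site["auth_seq_id"].as_array(str)
    else:
        res_seq = site["label_seq_id"].as_array(str)
    x = site["Cartn_x"].as_array(float)
    y = site["Cartn_y"].as_array(float)
    z = site["Cartn_z"].as_array(float)
    occ = col("occupancy", str, default="")
    bfac = col("B_iso_or_equiv", str, default="")

    atoms: list[Atom] = []
    for i in range(n):
        try:
            atoms.append(
                Atom(
                    serial=int(serial[i]) if serial is not None and serial[i] not in (".", "?") else i + 1,
                    name=str(name[i]),
                    element=(str(element[i]).capitalize() if element is not None else _element_from_name(str(name[i]))),
                    res_name=str(res_name[i]),
                    res_seq=int(float(res_seq[i])) if res_seq[i] not in (".", "?") else 0,
                    chain_id=str(chain[i]),
                    position=np.array([x[i], y[i], z[i]]),
                    occupancy=float(occ[i]) if occ is not None and occ[i] not in (".", "?") else 1.0,
                    b_factor=float(bfac[i]) if bfac is not None and bfac[i] not in (".", "?") else 0.0,
                    hetatm=(str(group[i]) == "HETATM"),
                )
            )
        except ValueError as exc:
            raise StructureParseError(f"{path}: bad atom_site row {i + 1}: {exc}") from exc
    operators = _read_oper_list(block)
    return StructureModel(atoms=atoms, source_format="mmcif", biomt_operators=operators)


def _read_oper_list(block) -> Optional[list[BiomtOperator]]:
    if "pdbx_struct_oper_list" not in block:
        return None
    cat = block["pdbx_struct_oper_list"]
    try:
        n = len(cat["id"].as_array(str))
        operators = []
        for i in range(n):
            rot = np.array(
                [
                    [float(cat[f"matrix[{r}][{c}]"].as_array(str)[i]) for c in (1, 2, 3)]
                    for r in (1, 2, 3)
                ]
            )
            trans = np.array(
                [float(cat[f"vector[{r}]"].as_array(str)[i]) for r in (1, 2, 3)]
            )
            operators.append(BiomtOperator(rotation=rot, translation=trans))
        return operators
    except (KeyError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Writing


def write_structure(
    model: StructureModel,
    path: str | os.PathLike,
    format: str = "auto",
) -> None:
    """Write a model as PDB or mmCIF.

    ``auto`` chooses by extension, falling back to mmCIF whenever strict
    PDB limits (99,999 atoms; single-character chain ids) are exceeded.
    """
    if not model.atoms:
        raise StructureWriteError("refusing to write an empty model")
    path = os.fspath(path)
    fmt = format
    if fmt == "auto":
        ext = os.path.splitext(path)[1].lower()
        fmt = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
        if fmt == "pdb" and not _fits_strict_pdb(model):
            fmt = "mmcif"
    if fmt == "pdb":
        _write_pdb(model, path)
    elif fmt == "mmcif":
        _write_mmcif(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _fits_strict_pdb(model: StructureModel) -> bool:
    return len(model.atoms) <= 99999 and all(len(c) == 1 for c in model.chains)


def _write_pdb(model: StructureModel, path: str) -> None:
    if len(model.atoms) > 99999:
        raise StructureWriteError(
            f"{len(model.atoms)} atoms exceed the strict PDB serial limit; "
            "write mmCIF instead"
        )
    bad = [c for c in model.chains if len(c) != 1]
    if bad:
        raise StructureWriteError(
            f"chain ids {bad[:3]} do not fit the single-character PDB field; "
            "write mmCIF instead"
        )
    lines: list[str] = []
    if model.biomt_operators:
        lines.extend(_biomt_remarks(model.biomt_operators))
    for i, atom in enumerate(model.atoms, start=1):
        record = "HETATM" if atom.hetatm else "ATOM  "
        name = atom.name
        # PDB convention: 1-letter elements start at column 14.
        padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
        lines.append(
            f"{record}{i:5d} {padded:<4.4s} {atom.res_name:>3.3s} {atom.chain_id:1.1s}"
            f"{atom.res_seq:4d}    "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
            f"{atom.element.upper():>2.2s}"
        )
    lines.append("END")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def _biomt_remarks(operators: Iterable[BiomtOperator]) -> list[str]:
    lines = []
    for opnum, op in enumerate(operators, start=1):
        for row in range(3):
            m = op.rotation[row]
            t = op.translation[row]
            lines.append(
                f"REMARK 350   BIOMT{row + 1} {opnum:3d}"
                f"{m[0]:10.6f}{m[1]:10.6f}{m[2]:10.6f}     {t:10.5f}"
            )
    return lines


def _write_mmcif(model: StructureModel, path: str) -> None:
    import biotite.structure.io.pdbx as pdbx

    n = len(model.atoms)
    cat = {
        "group_PDB": np.array(["HETATM" if a.hetatm else "ATOM" for a in model.atoms]),
        "id": np.arange(1, n + 1).astype(str),
        "type_symbol": np.array([a.element.upper() for a in model.atoms]),
        "label_atom_id": np.array([a.name for a in model.atoms]),
        "label_comp_id": np.array([a.res_name for a in model.atoms]),
        "label_asym_id": np.array([a.chain_id for a in model.atoms]),
        "label_seq_id": np.array([str(a.res_seq) for a in model.atoms]),
        "auth_asym_id": np.array([a.chain_id for a in model.atoms]),
        "auth_seq_id": np.array([str(a.res_seq) for a in model.atoms]),
        "Cartn_x": np.array([f"{a.position[0]:.4f}" for a in model.atoms]),
        "Cartn_y": np.array([f"{a.position[1]:.4f}" for a in model.atoms]),
        "Cartn_z": np.array([f"{a.position[2]:.4f}" for a in model.atoms]),
        "occupancy": np.array([f"{a.occupancy:.2f}" for a in model.atoms]),
        "B_iso_or_equiv": np.array([f"{a.b_factor:.2f}" for a in model.atoms]),
    }
    cif = pdbx.CIFFile()
    block = pdbx.CIFBlock()
    block["atom_site"] = pdbx.CIFCategory(cat)
    if model.biomt_operators:
        ops = model.biomt_operators
        oper: dict[str, np.ndarray] = {
            "id": np.array([str(i + 1) for i in range(len(ops))]),
            "type": np.array(
                ["identity operation" if _is_identity(op) else "point symmetry operation" for op in ops]
            ),
        }
        for r in (1, 2, 3):
            for c in (1, 2, 3):
                oper[f"matrix[{r}][{c}]"] = np.array(
                    [f"{op.rotation[r - 1][c - 1]:.10f}" for op in ops]
                )
            oper[f"vector[{r}]"] = np.array(
                [f"{op.translation[r - 1]:.5f}" for op in ops]
            )
        block["pdbx_struct_oper_list"] = pdbx.CIFCategory(oper)
    cif["model"] = block
    cif.write(path)


def _is_identity(op: BiomtOperator, tol: float = 1e-6) -> bool:
    return np.allclose(op.rotation, np.eye(3), atol=tol) and np.allclose(
        op.translation, 0.0, atol=tol
    )


# ---------------------------------------------------------------------------
# Selection


def select_atoms(
    model: StructureModel | Sequence[Atom],
    chain: Optional[str] = None,
    res_range: Optional[tuple[int, int]] = None,
    atom_names: Optional[Iterable[str]] = None,
) -> list[Atom]:
    """Return atoms matching all supplied filters, order preserved.

    ``res_range`` is a 1-based inclusive ``(start, end)`` interval in
    author numbering.  An empty selection is a legal value, not an error.
    """
    atoms = model.atoms if isinstance(model, StructureModel) else list(model)
    names = set(atom_names) if atom_names is not None else None
    out = []
    for atom in atoms:
        if chain is not None and atom.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= atom.res_seq <= res_range[1]):
            continue
        if names is not None and atom.name not in names:
            continue
        out.append(atom)
    return out
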