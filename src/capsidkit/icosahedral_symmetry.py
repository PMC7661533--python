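"""The 60-element icosahedral rotation group and capsid expansion.

The default frame is the ``I222`` setting: three mutually perpendicular
two-fold axes along x, y and z, five-folds along (0, ±1, ±φ) and cyclic
permutations, with φ the golden ratio.  Operators parsed from a
deposited file (REMARK 350 / ``_pdbx_struct_oper_list``) can be wrapped
into the same interface so measurements use the file's own symmetry
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .structure_io import Atom, BiomtOperator, StructureModel, select_atoms

__all__ = [
    "GROUP_ORDER",
    "SymmetryTolerances",
    "SymmetryOperatorSet",
    "SymmetryAxis",
    "generate_operators",
    "operators_from_biomt",
    "expand_capsid",
    "extract_copy",
    "find_axes",
    "symmetry_mate_distance",
    "biomt_text",
]

GROUP_ORDER = 60
_PHI = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class SymmetryTolerances:
    """Numerical tolerances used across group checks (one shared record)."""

    composition: float = 1e-6
    orthogonality: float = 1e-9
    angle: float = 1e-6


TOL = SymmetryTolerances()


@dataclass
class SymmetryOperatorSet:
    """A set of rigid rotations (plus optional translations) forming I.

    ``rotations`` has shape (n, 3, 3).  ``translations`` is zero for
    generated operator sets and carries the file's vectors for
    BIOMT-derived sets (expected ~0 for icosahedral depositions).
    """

    rotations: np.ndarray
    convention: str = "I222"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n, 3, 3)")
        if self.translations is None:
            self.translations = np.zeros((len(self.rotations), 3))
        else:
            self.translations = np.asarray(self.translations, dtype=float)

    def __len__(self) -> int:
        return len(self.rotations)

    def apply(self, index: int, coords: np.ndarray) -> np.ndarray:
        """Image of ``coords`` under operator ``index``."""
        shifted = np.asarray(coords, dtype=float) - self.origin
        return shifted @ self.rotations[index].T + self.translations[index] + self.origin

    def identity_index(self) -> int:
        for i, rot in enumerate(self.rotations):
            if np.allclose(rot, np.eye(3), atol=TOL.composition) and np.allclose(
                self.translations[i], 0.0, atol=1e-3
            ):
                return i
        raise ValueError("operator set does not contain the identity")

    def rotation_angles(self) -> np.ndarray:
        """Rotation angle of each operator in radians, in [0, π]."""
        traces = np.trace(self.rotations, axis1=1, axis2=2)
        return np.arccos(np.clip((traces - 1.0) / 2.0, -1.0, 1.0))

    def validate(self) -> None:
        """Check the group axioms numerically (orthogonality, closure,
        identity, inverses)."""
        rots = self.rotations
        eye = np.eye(3)
        for i, rot in enumerate(rots):
            if not np.allclose(rot @ rot.T, eye, atol=TOL.orthogonality):
                raise ValueError(f"operator {i} is not orthogonal")
            if abs(np.linalg.det(rot) - 1.0) > 1e-6:
                raise ValueError(f"operator {i} is not a proper rotation")
        self.identity_index()
        keys = {_matrix_key(rot) for rot in rots}
        if len(keys) != len(rots):
            raise ValueError("operator set contains duplicates")
        for i in range(len(rots)):
            for j in range(len(rots)):
                if _matrix_key(rots[i] @ rots[j]) not in keys:
                    raise ValueError(f"closure violated for product ({i}, {j})")
            if _matrix_key(rots[i].T) not in keys:
                raise ValueError(f"inverse of operator {i} missing")


@dataclass(frozen=True)
class SymmetryAxis:
    """A rotation axis through the origin; ``order`` ∈ {2, 3, 5}."""

    order: int
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))


def _matrix_key(rot: np.ndarray, decimals: int = 5) -> tuple:
    return tuple(np.round(rot, decimals).ravel() + 0.0)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return (
        np.eye(3) * np.cos(angle)
        + np.sin(angle) * cross
        + (1 - np.cos(angle)) * np.outer(axis, axis)
    )


def generate_operators(convention: str = "I222") -> SymmetryOperatorSet:
    """Build the 60 proper rotations of the icosahedral group.

    ``I222`` (alias ``I``): two-folds on the coordinate axes, five-folds
    along (0, ±1, ±φ) and cyclic permutations.  The group is closed from
    three generators by breadth-first multiplication.
    """
    if convention not in ("I222", "I"):
        raise ValueError(f"unsupported symmetry convention {convention!r}")
    generators = [
        np.diag([-1.0, -1.0, 1.0]),  # two-fold on z
        np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),  # three-fold on (1,1,1)
        _rodrigues(np.array([0.0, 1.0, _PHI]), 2.0 * np.pi / 5.0),  # five-fold
    ]
    members: dict[tuple, np.ndarray] = {_matrix_key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for rot in frontier:
            for gen in generators:
                prod = gen @ rot
                key = _matrix_key(prod)
                if key not in members:
                    members[key] = prod
                    nxt.append(prod)
        frontier = nxt
        if len(members) > GROUP_ORDER:  # pragma: no cover - construction guard
            raise RuntimeError("group closure exceeded order 60; bad generators")
    rotations = np.stack(list(members.values()))
    if len(rotations) != GROUP_ORDER:  # pragma: no cover - construction guard
        raise RuntimeError(f"expected 60 operators, got {len(rotations)}")
    # Identity first, then a deterministic order.
    order = np.lexsort(np.round(rotations.reshape(60, 9), 9).T[::-1])
    rotations = rotations[order]
    ident = next(
        i for i, rot in enumerate(rotations) if np.allclose(rot, np.eye(3), atol=1e-9)
    )
    rotations[[0, ident]] = rotations[[ident, 0]]
    return SymmetryOperatorSet(rotations=rotations, convention="I222")


def operators_from_biomt(
    operators: Sequence[BiomtOperator], convention: str = "file"
) -> SymmetryOperatorSet:
    """Wrap file-parsed assembly operators for symmetry measurements."""
    if not operators:
        raise ValueError("no assembly operators supplied")
    rots = np.stack([op.rotation for op in operators])
    trans = np.stack([op.translation for op in operators])
    for i, op in enumerate(operators):
        if not op.is_proper_rotation(tol=1e-4):
            raise ValueError(f"assembly operator {i + 1} is not a proper rotation")
    return SymmetryOperatorSet(rotations=rots, convention=convention, translations=trans)


# ---------------------------------------------------------------------------
# Expansion


def expand_capsid(au: StructureModel, ops: SymmetryOperatorSet) -> StructureModel:
    """Apply every operator to the asymmetric unit.

    Copy ``k`` of chain ``X`` is renamed ``X_k``; copy 0 is the identity
    image, so ``extract_copy(expanded, 0)`` reproduces the input exactly.
    """
    if not au.atoms:
        raise ValueError("cannot expand an empty asymmetric unit")
    ident = ops.identity_index()
    order = [ident] + [k for k in range(len(ops)) if k != ident]
    coords = au.coords()
    atoms: list[Atom] = []
    serial = 1
    for copy_idx, k in enumerate(order):
        imaged = ops.apply(k, coords)
        for atom, pos in zip(au.atoms, imaged):
            atoms.append(
                replace(
                    atom,
                    serial=serial,
                    chain_id=f"{atom.chain_id}_{copy_idx}",
                    position=pos,
                )
            )
            serial += 1
    return StructureModel(atoms=atoms, source_format="memory")


def extract_copy(expanded: StructureModel, copy_index: int) -> StructureModel:
    """Pull one symmetry copy back out of an expanded capsid."""
    suffix = f"_{copy_index}"
    atoms = [
        replace(a, chain_id=a.chain_id[: -len(suffix)])
        for a in expanded.atoms
        if a.chain_id.endswith(suffix)
    ]
    return StructureModel(atoms=atoms, source_format="memory")


def original_chain(chain_id: str) -> str:
    """Strip the ``_k`` copy suffix added by :func:`expand_capsid`."""
    head, sep, tail = chain_id.rpartition("_")
    if sep and tail.isdigit():
        return head
    return chain_id


# ---------------------------------------------------------------------------
# Axes


def find_axes(ops: SymmetryOperatorSet) -> list[SymmetryAxis]:
    """Enumerate the symmetry axes: 15 two-folds, 10 three-folds, 6
    five-folds, one sign-normalized direction per axis."""
    axes: list[SymmetryAxis] = []
    seen: list[tuple[int, np.ndarray]] = []
    angles = ops.rotation_angles()
    for rot, angle in zip(ops.rotations, angles):
        if angle < 1e-6:
            continue
        order = _axis_order(angle)
        direction = _rotation_axis(rot, angle)
        direction = _normalize_sign(direction)
        if any(o == order and np.allclose(direction, d, atol=1e-6) for o, d in seen):
            continue
        seen.append((order, direction))
        axes.append(SymmetryAxis(order=order, direction=direction))
    return axes


def _axis_order(angle: float) -> int:
    for order in (2, 3, 5):
        base = 2.0 * np.pi / order
        k = round(angle / base)
        if k >= 1 and abs(angle - k * base) < 1e-6:
            # angle must be a multiple of 2π/order that is not a multiple
            # of a smaller-order fraction (π itself only matches order 2)
            if order == 5 and abs(angle - np.pi) < 1e-6:
                continue
            return order
    raise ValueError(f"rotation angle {angle:.6f} rad is not icosahedral")


def _rotation_axis(rot: np.ndarray, angle: float) -> np.ndarray:
    if abs(angle - np.pi) > 1e-6:
        axis = np.array(
            [rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]]
        ) / (2.0 * np.sin(angle))
    else:
        outer = (rot + np.eye(3)) / 2.0
        col = int(np.argmax(np.diag(outer)))
        axis = outer[:, col]
    return axis / np.linalg.norm(axis)


def _normalize_sign(direction: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    for component in (2, 0, 1):
        if abs(direction[component]) > tol:
            return direction if direction[component] > 0 else -direction
    return direction  # pragma: no cover - zero vector cannot reach here


# ---------------------------------------------------------------------------
# Distances


def symmetry_mate_distance(
    au: StructureModel,
    ops: SymmetryOperatorSet,
    chain: str,
    res_seq: int,
    atom_name: str,
    axis_order: Literal[2, 3, 5, "nearest"] = "nearest",
) -> float:
    """Distance (Å) from one atom to its closest symmetry mate.

    ``axis_order`` restricts images to one rotation class (2, 3 or 5);
    ``"nearest"`` takes the minimum over all non-identity images.  The
    selection must resolve to exactly one atom.
    """
    picked = select_atoms(au, chain=chain, res_range=(res_seq, res_seq), atom_names={atom_name})
    if len(picked) != 1:
        raise ValueError(
            f"selection chain={chain!r} res={res_seq} atom={atom_name!r} matched "
            f"{len(picked)} atoms; need exactly 1"
        )
    point = picked[0].position
    angles = ops.rotation_angles()
    best = np.inf
    for k in range(len(ops)):
        if angles[k] < 1e-6 and np.allclose(ops.translations[k], 0.0, atol=1e-3):
            continue  # identity
        if axis_order != "nearest" and _matches_class(angles[k], int(axis_order)) is False:
            continue
        image = ops.apply(k, point)
        best = min(best, float(np.linalg.norm(image - point)))
    if not np.isfinite(best):
        raise ValueError(f"no operators of class {axis_order} in the set")
    return best


def _matches_class(angle: float, order: int) -> bool:
    if order not in (2, 3, 5):
        raise ValueError("axis order must be 2, 3 or 5")
    base = 2.0 * np.pi / order
    k = round(angle / base)
    if k < 1 or k >= order:
        return False
    if order == 5 and abs(angle - np.pi) < 1e-6:
        return False
    return abs(angle - k * base) < 1e-5


# ---------------------------------------------------------------------------
# Export


def biomt_text(ops: SymmetryOperatorSet) -> str:
    """Render the operator set as REMARK 350 BIOMT lines."""
    from .structure_io import _biomt_remarks  # shared formatter

    biomt = [
        BiomtOperator(rotation=ops.rotations[i], translation=ops.translations[i])
        for i in range(len(ops))
    ]
    return "\n".join(_biomt_remarks(biomt)) + "\n"


def to_biomt_operators(ops: SymmetryOperatorSet) -> list[BiomtOperator]:
    """Convert to :class:`BiomtOperator` records for file output."""
    return [
        BiomtOperator(rotation=ops.rotations[i], translation=ops.translations[i])
        for i in range(len(ops))
    ]
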