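"""Solvent-accessible surface area, buried interface area and contact
networks.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
generalized-spiral point set (no RNG), so results are bit-reproducible
for a fixed point count.  Buried surface area between two atom sets is
(SASA_A + SASA_B − SASA_AB) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .icosahedral_symmetry import (
    SymmetryAxis,
    SymmetryOperatorSet,
    expand_capsid,
    find_axes,
    original_chain,
)
from .structure_io import Atom, StructureModel, atoms_coords

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "ContactEdge",
    "sphere_spiral_points",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "capsid_buried_area",
    "contact_network",
    "axis_neighborhood_report",
]

# Standard protein heavy-atom van der Waals radii (Å); overridable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Se": 1.90,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Mg": 1.73,
    "Zn": 1.39,
    "Fe": 1.40,
    "Ca": 2.31,
    "Na": 2.27,
    "K": 2.75,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_CONTACT_CUTOFF = 4.0


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible area (Å²)."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass(frozen=True)
class ContactEdge:
    """A residue–residue contact with the closest heavy-atom distance."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    min_distance: float
    n_atom_pairs: int


def sphere_spiral_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _atom_radii(
    atoms: Sequence[Atom], radii_table: Optional[dict[str, float]]
) -> np.ndarray:
    table = VDW_RADII if radii_table is None else radii_table
    radii = np.empty(len(atoms))
    missing = set()
    for i, atom in enumerate(atoms):
        element = atom.element.capitalize()
        if element in table:
            radii[i] = table[element]
        elif element.upper() in table:
            radii[i] = table[element.upper()]
        else:
            missing.add(atom.element)
            radii[i] = np.nan
    if missing:
        raise ValueError(
            f"no van der Waals radius for element(s): {sorted(missing)}; "
            "supply a radii_table entry"
        )
    return radii


def shrake_rupley_sasa(
    atoms: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: Optional[dict[str, float]] = None,
) -> SasaResult:
    """Shrake–Rupley SASA of an atom collection.

    For every atom, ``n_points`` test points are placed on its expanded
    sphere (vdW + probe); points inside any neighbour's expanded sphere
    are occluded.  Accessible area = unoccluded fraction × 4πr².
    """
    if len(atoms) == 0:
        raise ValueError("SASA of an empty atom collection is undefined")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords = atoms_coords(atoms)
    radii = _atom_radii(atoms, radii_table) + probe
    unit = sphere_spiral_points(n_points)

    tree = cKDTree(coords)
    r_max = float(radii.max())
    # neighbour pairs that can possibly occlude each other
    pairs = tree.query_ball_tree(tree, 2.0 * r_max)

    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        neigh = [j for j in pairs[i] if j != i]
        if neigh:
            nb = np.asarray(neigh)
            delta = coords[nb] - coords[i]
            dist = np.linalg.norm(delta, axis=1)
            keep = dist < radii[i] + radii[nb]
            nb = nb[keep]
        else:
            nb = np.empty(0, dtype=int)
        sphere = coords[i] + radii[i] * unit
        if len(nb):
            d2 = (
                (sphere[:, None, :] - coords[nb][None, :, :]) ** 2
            ).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points
    return SasaResult(per_atom_area=areas, probe_radius=probe, n_sphere_points=n_points)


def buried_surface_area(
    set_a: Sequence[Atom],
    set_b: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: Optional[dict[str, float]] = None,
) -> float:
    """Interface area (Å²) buried between two disjoint atom sets:
    (SASA_A + SASA_B − SASA_AB) / 2."""
    ids_a = {id(a) for a in set_a}
    if any(id(b) in ids_a for b in set_b):
        raise ValueError("atom sets overlap; buried area needs disjoint sets")
    kwargs = dict(probe=probe, n_points=n_points, radii_table=radii_table)
    sasa_a = shrake_rupley_sasa(set_a, **kwargs).total
    sasa_b = shrake_rupley_sasa(set_b, **kwargs).total
    sasa_ab = shrake_rupley_sasa(list(set_a) + list(set_b), **kwargs).total
    return max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)


def capsid_buried_area(
    au: StructureModel,
    ops: SymmetryOperatorSet,
    mode: Literal["per_asym_unit_neighbors", "total"] = "per_asym_unit_neighbors",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: Optional[dict[str, float]] = None,
    contact_prefilter: float = 8.0,
) -> float:
    """Buried area (10³ nm²) between one asymmetric unit and its
    symmetry neighbours.

    Every AU–copy interface is counted once.  ``per_asym_unit_neighbors``
    sums the interfaces of copy 0 with each contacting copy;
    ``total`` scales to the whole capsid (60 AUs, each interface shared
    by two: × 30).
    """
    if mode not in ("per_asym_unit_neighbors", "total"):
        raise ValueError(f"unknown mode {mode!r}")
    expanded = expand_capsid(au, ops)
    n_au = len(au.atoms)
    coords = expanded.coords()
    base = coords[:n_au]
    tree0 = cKDTree(base)
    total_bsa = 0.0
    base_atoms = expanded.atoms[:n_au]
    for k in range(1, len(ops)):
        copy_coords = coords[k * n_au : (k + 1) * n_au]
        tree_k = cKDTree(copy_coords)
        if not tree0.count_neighbors(tree_k, contact_prefilter):
            continue
        copy_atoms = expanded.atoms[k * n_au : (k + 1) * n_au]
        total_bsa += buried_surface_area(
            base_atoms, copy_atoms, probe=probe, n_points=n_points, radii_table=radii_table
        )
    if mode == "total":
        total_bsa *= len(ops) / 2.0
    return total_bsa / 1e5  # Å² -> 10³ nm²


def contact_network(
    expanded: StructureModel | Sequence[Atom],
    group_a: Sequence[Atom],
    group_b: Sequence[Atom],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[ContactEdge]:
    """Residue-level contacts between two atom selections.

    Returns one edge per residue pair having any inter-atomic distance
    ≤ ``cutoff``, with the per-pair minimum distance and the number of
    atom pairs within the cutoff.  KD-tree indexed, so full capsids are
    fine.  ``expanded`` is accepted for interface symmetry with the CLI
    but the selections carry all needed information.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not group_a or not group_b or cutoff == 0.0:
        return []
    coords_a = atoms_coords(group_a)
    coords_b = atoms_coords(group_b)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, cutoff)
    best: dict[tuple, tuple[float, int]] = {}
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        atom_a = group_a[i]
        key_a = (atom_a.chain_id, atom_a.res_seq, atom_a.res_name)
        for j in hits:
            atom_b = group_b[j]
            key_b = (atom_b.chain_id, atom_b.res_seq, atom_b.res_name)
            if key_a == key_b:
                continue
            dist = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if dist > cutoff:
                continue
            key = (key_a, key_b)
            if key in best:
                prev_d, prev_n = best[key]
                best[key] = (min(prev_d, dist), prev_n + 1)
            else:
                best[key] = (dist, 1)
    edges = [
        ContactEdge(residue_a=a, residue_b=b, min_distance=d, n_atom_pairs=n)
        for (a, b), (d, n) in sorted(best.items())
    ]
    return edges


def axis_neighborhood_report(
    au: StructureModel,
    ops: SymmetryOperatorSet,
    chain_map: Optional[dict[str, str]] = None,
    radius_shell: float = 15.0,
    axis_orders: Iterable[int] = (2, 3, 5),
) -> dict[int, list[tuple[str, int]]]:
    """Which chains populate the neighbourhood of each symmetry axis
    class.

    For every axis of each requested order, atoms of the expanded capsid
    within a cylinder of radius ``radius_shell`` around the axis are
    tallied by their original chain (mapped through ``chain_map`` when
    given).  Returns, per axis order, ``(chain_label, atom_count)``
    pairs ranked by count.
    """
    expanded = expand_capsid(au, ops)
    coords = expanded.coords()
    labels = np.array(
        [
            (chain_map or {}).get(original_chain(a.chain_id), original_chain(a.chain_id))
            for a in expanded.atoms
        ]
    )
    axes = find_axes(ops)
    report: dict[int, list[tuple[str, int]]] = {}
    for order in axis_orders:
        tally: dict[str, int] = {}
        for axis in axes:
            if axis.order != order:
                continue
            # distance from the line through the origin along axis.direction
            proj = coords @ axis.direction
            perp = coords - np.outer(proj, axis.direction)
            near = np.linalg.norm(perp, axis=1) <= radius_shell
            for label in labels[near]:
                tally[label] = tally.get(label, 0) + 1
        report[order] = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return report
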