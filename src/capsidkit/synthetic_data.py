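"""Seed-deterministic synthetic fixtures: ideal capsid shells with
known geometry, interface fixtures with closed-form buried areas, and
pseudo-random polyprotein sequences.

Every fixture ships its ground truth so geometry, SASA and distance
operations can be verified against closed forms without any downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .icosahedral_symmetry import SymmetryOperatorSet, expand_capsid, generate_operators
from .structure_io import Atom, StructureModel

__all__ = [
    "ShellSpec",
    "ShellGroundTruth",
    "ShellCapsid",
    "InterfaceFixture",
    "make_shell_capsid",
    "make_interface_fixture",
    "make_polyprotein",
]

_AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class ShellSpec:
    """Parameters of a synthetic icosahedral shell.

    ``atoms_per_au`` atoms are placed in one asymmetric wedge at radii
    uniform in [inner_radius, outer_radius]; expansion yields an exactly
    symmetric shell of 60 × ``atoms_per_au`` atoms.
    """

    inner_radius: float = 100.0
    outer_radius: float = 130.0
    atoms_per_au: int = 500
    n_chains_per_au: int = 3
    seed: int = 0
    surface_coverage: float = 8.0  # target mean nearest-neighbour spacing, Å
    min_image_spacing: float = 0.5  # reject wedge-boundary clashes, Å

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.atoms_per_au < self.n_chains_per_au:
            raise ValueError("atoms_per_au must be >= n_chains_per_au")
        if self.n_chains_per_au < 1 or self.n_chains_per_au > len(_CHAIN_IDS):
            raise ValueError("unsupported chain count")


@dataclass(frozen=True)
class ShellGroundTruth:
    """True geometry of a generated shell, recorded at build time."""

    inner_radius: float
    outer_radius: float
    r_min: float
    r_max: float
    n_atoms_expanded: int
    mean_spacing: float
    sparse: bool  # True when spacing misses the coverage target


class ShellCapsid(NamedTuple):
    au: StructureModel
    ops: SymmetryOperatorSet
    ground_truth: ShellGroundTruth


@dataclass(frozen=True)
class InterfaceFixture:
    """Two atom sets plus the analytic buried area they should produce."""

    set_a: list[Atom]
    set_b: list[Atom]
    expected_bsa: float
    radii_table: dict[str, float]
    probe: float
    tolerance: float  # relative, appropriate to the fixture kind


def make_shell_capsid(spec: ShellSpec) -> ShellCapsid:
    """Build a three-chain asymmetric unit of an ideal icosahedral shell.

    Atom directions are rejection-sampled (seeded) inside the canonical
    asymmetric wedge — a direction is accepted when it is the
    lexicographic maximum of its 60-image orbit — with a minimum
    inter-image spacing so expansion produces no boundary clashes.
    """
    ops = generate_operators()
    rng = np.random.default_rng(spec.seed)
    rots = ops.rotations
    directions = np.empty((spec.atoms_per_au, 3))
    radii = np.empty(spec.atoms_per_au)
    count = 0
    attempts = 0
    max_attempts = 20000 * spec.atoms_per_au
    mean_radius = 0.5 * (spec.inner_radius + spec.outer_radius)
    while count < spec.atoms_per_au:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - safety valve
            raise RuntimeError("wedge rejection sampling failed to converge")
        vec = rng.normal(size=3)
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            continue
        direction = vec / norm
        images = rots @ direction
        order = np.lexsort((images[:, 2], images[:, 1], images[:, 0]))
        top = images[order[-1]]
        if not np.allclose(top, direction, atol=1e-9):
            continue  # not the canonical orbit representative
        # keep clear of the wedge boundary: nearest own image at mean radius
        image_dist = np.linalg.norm(images - direction, axis=1)
        nearest_image = np.min(image_dist[image_dist > 1e-9]) * mean_radius
        if nearest_image < spec.min_image_spacing:
            continue
        directions[count] = direction
        radii[count] = rng.uniform(spec.inner_radius, spec.outer_radius)
        count += 1

    coords = directions * radii[:, None]
    atoms: list[Atom] = []
    per_chain = -(-spec.atoms_per_au // spec.n_chains_per_au)  # ceil
    for i in range(spec.atoms_per_au):
        chain = _CHAIN_IDS[i // per_chain]
        res_seq = i % per_chain + 1
        atoms.append(
            Atom(
                serial=i + 1,
                name="CA",
                element="C",
                res_name="ALA",
                res_seq=res_seq,
                chain_id=chain,
                position=coords[i],
            )
        )
    au = StructureModel(atoms=atoms, source_format="memory")

    expanded = expand_capsid(au, ops)
    exp_coords = expanded.coords()
    exp_radii = np.linalg.norm(exp_coords, axis=1)
    mean_spacing = _mean_nn_spacing(exp_coords)
    truth = ShellGroundTruth(
        inner_radius=spec.inner_radius,
        outer_radius=spec.outer_radius,
        r_min=float(exp_radii.min()),
        r_max=float(exp_radii.max()),
        n_atoms_expanded=len(expanded.atoms),
        mean_spacing=mean_spacing,
        sparse=mean_spacing > spec.surface_coverage,
    )
    return ShellCapsid(au=au, ops=ops, ground_truth=truth)


def _mean_nn_spacing(coords: np.ndarray, sample: int = 2000) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    if len(coords) > sample:
        idx = np.linspace(0, len(coords) - 1, sample).astype(int)
        query = coords[idx]
    else:
        query = coords
    dist, _ = tree.query(query, k=2)
    return float(dist[:, 1].mean())


# ---------------------------------------------------------------------------
# Interface fixtures


def make_interface_fixture(
    kind: str,
    probe: float = 1.4,
    # two_spheres parameters
    radius_a: float = 5.0,
    radius_b: float = 8.0,
    distance: Optional[float] = None,
    # two_slabs parameters
    slab_n: int = 40,
    slab_spacing: float = 1.2,
    slab_atom_radius: float = 1.7,
    slab_gap: float = 2.0,
) -> InterfaceFixture:
    """Build an interface fixture with a closed-form expected buried
    area.

    ``two_spheres``: two single atoms of custom radii at ``distance``;
    the expected buried area is the mean of the two spherical caps cut
    by the plane of intersection of the probe-expanded spheres.

    ``two_slabs``: two square single-layer atom grids face to face with
    a vertical gap too narrow for the probe; the expected buried area is
    the facing planar area of the probe-expanded slab,
    ((n−1)·spacing + 2·(r_atom + probe))², i.e. the atom-centre square
    dilated by the expanded sphere radius on each side.
    """
    if kind == "two_spheres":
        big_a, big_b = radius_a + probe, radius_b + probe
        if distance is None:
            distance = 0.8 * (big_a + big_b)
        if distance <= abs(big_a - big_b):
            raise ValueError("one probe-expanded sphere engulfs the other")
        set_a = [
            Atom(1, "XA", "Xa", "FXA", 1, "A", np.zeros(3))
        ]
        set_b = [
            Atom(2, "XB", "Xb", "FXB", 1, "B", np.array([distance, 0.0, 0.0]))
        ]
        table = {"Xa": radius_a, "Xb": radius_b}
        expected = _two_sphere_bsa(big_a, big_b, distance)
        return InterfaceFixture(
            set_a=set_a, set_b=set_b, expected_bsa=expected,
            radii_table=table, probe=probe, tolerance=0.02,
        )
    if kind == "two_slabs":
        if slab_gap >= 2.0 * probe + 2.0 * slab_atom_radius:
            raise ValueError("gap admits the probe; slabs would not bury area")
        offsets = (np.arange(slab_n) - (slab_n - 1) / 2.0) * slab_spacing
        xx, yy = np.meshgrid(offsets, offsets, indexing="ij")
        grid = np.column_stack([xx.ravel(), yy.ravel()])
        set_a = [
            Atom(i + 1, "CS", "C", "SLB", i + 1, "A", np.array([x, y, 0.0]))
            for i, (x, y) in enumerate(grid)
        ]
        set_b = [
            Atom(i + 1, "CS", "C", "SLB", i + 1, "B", np.array([x, y, slab_gap]))
            for i, (x, y) in enumerate(grid)
        ]
        expected = ((slab_n - 1) * slab_spacing + 2.0 * (slab_atom_radius + probe)) ** 2
        return InterfaceFixture(
            set_a=set_a, set_b=set_b, expected_bsa=expected,
            radii_table={"C": slab_atom_radius}, probe=probe, tolerance=0.05,
        )
    raise ValueError(f"unknown interface fixture kind {kind!r}")


def _two_sphere_bsa(big_a: float, big_b: float, distance: float) -> float:
    """Mean of the two spherical caps buried when probe-expanded spheres
    of radii ``big_a``/``big_b`` intersect at centre distance
    ``distance``."""
    if distance >= big_a + big_b:
        return 0.0
    x_a = (distance**2 + big_a**2 - big_b**2) / (2.0 * distance)
    cap_a = 2.0 * math.pi * big_a * (big_a - x_a)
    x_b = (distance**2 + big_b**2 - big_a**2) / (2.0 * distance)
    cap_b = 2.0 * math.pi * big_b * (big_b - x_b)
    return 0.5 * (cap_a + cap_b)


# ---------------------------------------------------------------------------
# Sequences


def make_polyprotein(length: int, seed: int = 0) -> str:
    """Reproducible pseudo-random 20-letter amino-acid sequence."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_AMINO_LETTERS), size=length)
    return "".join(letters)
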