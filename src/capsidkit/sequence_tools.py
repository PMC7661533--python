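"""Polyprotein cleavage arithmetic, fragment masses, inner-surface
charge mapping and modeled-residue accounting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .icosahedral_symmetry import SymmetryAxis
from .structure_io import Atom, StructureModel

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "CleavageProduct",
    "ChargedResidueSite",
    "ResidueAccounting",
    "cleave_polyprotein",
    "approx_mass",
    "basic_residue_map",
    "modeled_residue_accounting",
    "read_fasta",
]

# Average (not monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "X": 110.0,
}
WATER_MASS = 18.0153

# Basic residues and the side-chain atom taken as the charge carrier.
_BASIC_TERMINAL_ATOM = {"LYS": "NZ", "ARG": "CZ", "HIS": "NE2"}


@dataclass(frozen=True)
class CleavageProduct:
    """One mature fragment of a cleaved polyprotein (1-based inclusive
    coordinates)."""

    name: str
    start: int
    end: int
    sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def approx_mass(self) -> Optional[float]:
        return approx_mass(self.sequence) if self.sequence is not None else None


@dataclass(frozen=True)
class ChargedResidueSite:
    """A basic residue (ARG/LYS/HIS) located on the capsid inner
    surface."""

    chain: str
    res_seq: int
    res_name: str
    radial_position: float
    nearest_axis: tuple[int, float]


@dataclass(frozen=True)
class ResidueAccounting:
    """Modeled-residue bookkeeping for one chain (CA-bearing residues)."""

    first_modeled: int
    last_modeled: int
    modeled_count: int
    expected_count: int

    @property
    def disordered_count(self) -> int:
        return self.expected_count - self.modeled_count


def cleave_polyprotein(
    length_or_sequence: int | str,
    sites: Sequence[int],
    names: Optional[Sequence[str]] = None,
) -> list[CleavageProduct]:
    """Cut a polyprotein after each position in ``sites``.

    "Cleaved at position s" means the bond after residue s, so a
    931-residue chain cut at [264, 515] yields fragments of 264, 251 and
    416 residues.  Products tile the input without gaps or overlaps.
    """
    if isinstance(length_or_sequence, str):
        sequence: Optional[str] = length_or_sequence
        length = len(sequence)
    else:
        sequence = None
        length = int(length_or_sequence)
    if length < 1:
        raise ValueError("polyprotein length must be >= 1")
    sites = list(sites)
    if any(s2 <= s1 for s1, s2 in zip(sites, sites[1:])):
        raise ValueError("cleavage sites must be strictly ascending")
    if any(not (0 < s < length) for s in sites):
        raise ValueError(f"cleavage sites must lie strictly inside (0, {length})")
    bounds = [0] + sites + [length]
    n_products = len(bounds) - 1
    if names is None:
        names = [f"fragment_{i + 1}" for i in range(n_products)]
    elif len(names) != n_products:
        raise ValueError(f"need {n_products} names, got {len(names)}")
    products = []
    for i in range(n_products):
        start, end = bounds[i] + 1, bounds[i + 1]
        products.append(
            CleavageProduct(
                name=names[i],
                start=start,
                end=end,
                sequence=sequence[start - 1 : end] if sequence is not None else None,
            )
        )
    return products


def approx_mass(sequence: str) -> float:
    """Approximate average mass of a peptide in kDa (residue masses plus
    one water)."""
    total = WATER_MASS
    for pos, letter in enumerate(sequence.upper(), start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise ValueError(
                f"illegal residue {letter!r} at position {pos}"
            ) from None
    return total / 1000.0


def basic_residue_map(
    expanded: StructureModel,
    axes: Iterable[SymmetryAxis],
    inner_shell: tuple[float, float],
) -> list[ChargedResidueSite]:
    """Locate basic residues whose side-chain terminal atom sits in the
    radial interval ``inner_shell`` (Å), annotated with the nearest
    symmetry axis.

    Terminal atoms: NZ (LYS), CZ (ARG), NE2 (HIS); CB as fallback when
    the side chain is incomplete.
    """
    lo, hi = inner_shell
    if lo > hi:
        raise ValueError("inner_shell interval is inverted")
    axes = list(axes)
    per_residue: dict[tuple[str, int, str], dict[str, Atom]] = {}
    for atom in expanded.atoms:
        if atom.res_name in _BASIC_TERMINAL_ATOM:
            per_residue.setdefault(
                (atom.chain_id, atom.res_seq, atom.res_name), {}
            )[atom.name] = atom
    sites = []
    for (chain, res_seq, res_name), by_name in sorted(per_residue.items()):
        terminal = by_name.get(_BASIC_TERMINAL_ATOM[res_name]) or by_name.get("CB")
        if terminal is None:
            continue
        radius = float(np.linalg.norm(terminal.position))
        if not (lo <= radius <= hi):
            continue
        nearest = min(
            (
                (axis.order, _axis_distance(terminal.position, axis.direction))
                for axis in axes
            ),
            key=lambda pair: pair[1],
            default=(0, float("inf")),
        )
        sites.append(
            ChargedResidueSite(
                chain=chain,
                res_seq=res_seq,
                res_name=res_name,
                radial_position=radius,
                nearest_axis=nearest,
            )
        )
    return sites


def _axis_distance(point: np.ndarray, direction: np.ndarray) -> float:
    proj = float(point @ direction)
    return float(np.linalg.norm(point - proj * direction))


def modeled_residue_accounting(
    model: StructureModel,
    chain_map: dict[str, str],
    expected_lengths: dict[str, int],
) -> dict[str, ResidueAccounting]:
    """Per-protein modeled-residue ranges: residues possessing a CA
    atom, against the declared expected chain length."""
    by_protein: dict[str, set[int]] = {}
    chains_seen = set()
    for atom in model.atoms:
        if atom.name != "CA":
            continue
        chains_seen.add(atom.chain_id)
        if atom.chain_id in chain_map:
            by_protein.setdefault(chain_map[atom.chain_id], set()).add(atom.res_seq)
    missing = [p for p in expected_lengths if p not in by_protein]
    if missing:
        raise ValueError(
            f"no mapped chain found for protein(s) {missing}; model chains: "
            f"{sorted(chains_seen)}"
        )
    out = {}
    for protein, residues in by_protein.items():
        if protein not in expected_lengths:
            raise ValueError(f"no expected length declared for protein {protein!r}")
        out[protein] = ResidueAccounting(
            first_modeled=min(residues),
            last_modeled=max(residues),
            modeled_count=len(residues),
            expected_count=expected_lengths[protein],
        )
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reader: mapping of record id (first token) to
    sequence."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records
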