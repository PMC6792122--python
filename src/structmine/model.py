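"""Core domain types for decoded macromolecular structures.

Everything downstream (selectors, pruners, calculators, the parallel
engine) operates on these in-memory types:

* :class:`Atom` — one atom with name, element, charge and coordinates.
* :class:`Group` — one chemical group (a residue, ligand, ion or water)
  with its atoms and intra-group bonds.
* :class:`StructureEntry` — one decoded PDB entry: an ordered list of
  groups, chain labels, inter-group bonds and biological-assembly
  membership per chain.
* :class:`SelectionSet` — an ordered set of group indices within one
  entry; the currency passed between workflow stages.

Conventions: all group and atom indices are 0-based; ranges are
half-open; bond pairs are stored with the lower index first.  Element
symbols and chemical-component IDs are uppercase.  Composition types
(``chem_comp.type`` strings such as ``"L-PEPTIDE LINKING"`` or
``"NON-POLYMER"``) are stored verbatim, uppercased; classification
logic lives in :mod:`structmine.select`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "StructmineError",
    "EntryMismatchError",
    "Atom",
    "Group",
    "StructureEntry",
    "SelectionSet",
    "group_heavy_atom_count",
    "selection_intersect",
]

#: Elements that do not count as heavy atoms (hydrogen and deuterium).
_LIGHT_ELEMENTS = frozenset({"H", "D"})


class StructmineError(Exception):
    """Base class for all errors raised by this package."""


class EntryMismatchError(StructmineError):
    """Two selections from different entries were combined."""


@dataclass(frozen=True, slots=True)
class Atom:
    """One atom: text name (e.g. ``"CA"``), IUPAC element symbol
    (uppercase), integer formal charge and coordinates in Å."""

    name: str
    element: str
    formal_charge: int
    x: float
    y: float
    z: float

    @property
    def is_heavy(self) -> bool:
        """True for every element except hydrogen and deuterium."""
        return self.element not in _LIGHT_ELEMENTS

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True, slots=True)
class Group:
    """One chemical group (residue, ligand, ion or water).

    ``bonds`` holds intra-group bonds as ``(i, j, order)`` with
    0-based atom indices, ``i < j``, no self-bonds.
    """

    name: str
    comp_type: str
    seq_id: int
    chain_index: int
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i} in group {self.name}")
            if not (0 <= i < j < n):
                raise ValueError(
                    f"bond ({i}, {j}) out of range for group {self.name} "
                    f"with {n} atoms (pairs must be ordered i < j)"
                )

    def heavy_atoms(self) -> Iterator[tuple[int, Atom]]:
        """Yield ``(atom_index, atom)`` for every heavy atom."""
        for i, atom in enumerate(self.atoms):
            if atom.is_heavy:
                yield i, atom


@dataclass(frozen=True, slots=True)
class StructureEntry:
    """One decoded PDB entry (model 1 only).

    ``inter_group_bonds`` entries are
    ``((group_index, atom_index), (group_index, atom_index), order)``.
    ``assembly_map`` gives, per chain index, the biological-assembly
    copy label the chain belongs to (empty string when unassigned).
    """

    pdb_id: str
    groups: tuple[Group, ...]
    chain_ids: tuple[str, ...]
    inter_group_bonds: tuple[
        tuple[tuple[int, int], tuple[int, int], int], ...
    ] = ()
    assembly_map: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.groups)
        for (gi, ai), (gj, aj), _order in self.inter_group_bonds:
            for g, a in ((gi, ai), (gj, aj)):
                if not 0 <= g < n:
                    raise ValueError(f"bond references group {g} of {n}")
                if not 0 <= a < len(self.groups[g].atoms):
                    raise ValueError(
                        f"bond references atom {a} of group {g} "
                        f"({len(self.groups[g].atoms)} atoms)"
                    )
        for group in self.groups:
            if not 0 <= group.chain_index < len(self.chain_ids):
                raise ValueError(
                    f"group {group.name} references chain "
                    f"{group.chain_index} of {len(self.chain_ids)}"
                )
        if self.assembly_map and len(self.assembly_map) != len(self.chain_ids):
            raise ValueError("assembly_map length must match chain_ids")

    @property
    def n_atoms(self) -> int:
        return sum(len(g.atoms) for g in self.groups)

    def chain_assembly_label(self, chain_index: int) -> str:
        """Assembly-copy label for a chain; '' when no map is present."""
        if not self.assembly_map:
            return ""
        return self.assembly_map[chain_index]


@dataclass(frozen=True, slots=True)
class SelectionSet:
    """An ordered set of group indices within one entry.

    ``indices`` is strictly increasing (unique, sorted ascending); use
    :meth:`from_indices` to build one from an arbitrary iterable.
    """

    entry_id: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.indices, self.indices[1:]):
            if a >= b:
                raise ValueError(
                    f"selection indices must be strictly increasing, "
                    f"got {a} before {b}"
                )
        if self.indices and self.indices[0] < 0:
            raise ValueError("selection indices must be nonnegative")

    @classmethod
    def from_indices(cls, entry_id: str, indices: Iterable[int]) -> "SelectionSet":
        return cls(entry_id, tuple(sorted(set(indices))))

    @classmethod
    def empty(cls, entry_id: str) -> "SelectionSet":
        return cls(entry_id, ())

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, index: int) -> bool:
        return index in set(self.indices)

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices)

    def is_valid_for(self, entry: StructureEntry) -> bool:
        """Whether every index refers to a group of ``entry``."""
        n = len(entry.groups)
        return all(0 <= i < n for i in self.indices)


def group_heavy_atom_count(group: Group) -> int:
    """Number of heavy (non-H, non-D) atoms in a group.

    This is the "size" used by the group-level selectors; hydrogens
    are ignored because they are mostly absent from crystal structures
    and counting them would make selection resolution-dependent.
    """
    return sum(1 for atom in group.atoms if atom.is_heavy)


def selection_intersect(a: SelectionSet, b: SelectionSet) -> SelectionSet:
    """Set intersection of two selections over the same entry.

    Raises :class:`EntryMismatchError` when the selections come from
    different entries — silently intersecting across entries would be
    a workflow-composition bug.
    """
    if a.entry_id != b.entry_id:
        raise EntryMismatchError(
            f"cannot intersect selections from different entries: "
            f"{a.entry_id!r} vs {b.entry_id!r}"
        )
    other = set(b.indices)
    return SelectionSet(a.entry_id, tuple(i for i in a.indices if i in other))
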