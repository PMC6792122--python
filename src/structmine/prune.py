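"""Stage-2 pruners: shrink selections by redundancy, commonness and
3D environment.

Three ways to thin a selection before computing features:

* :func:`prune_identical_groups` — drop biologically identical copies
  of the same group across biological-assembly copies, keeping the
  lowest-index one;
* :func:`prune_common_groups` — drop ubiquitous crystallisation
  additives and ions by component ID;
* :func:`keep_interactions` — keep (or remove) groups with a heavy
  atom within a distance cutoff of another selection, accelerated by a
  cell list whose cubic cells have edge equal to the cutoff so each
  query scans only the 27 neighbouring cells.

All pruners are contractive (output ⊆ input) and pure.  Distance
comparisons are closed (``d ≤ cutoff``) and computed on squared
distances, which makes the cell-list result bit-identical to a naive
all-pairs scan.  Only heavy atoms participate in distance tests:
hydrogens are mostly absent from crystal structures, and including
them would make results resolution-dependent.
"""

from __future__ import annotations

from collections import defaultdict
from math import floor
from pathlib import Path
from typing import Iterable

from .model import SelectionSet, StructmineError, StructureEntry

__all__ = [
    "DEFAULT_COMMON_GROUPS",
    "CellGrid",
    "load_blocklist",
    "prune_identical_groups",
    "prune_common_groups",
    "keep_interactions",
]

#: Crystallisation additives and ions dropped by default; fully
#: user-replaceable (one-ID-per-line text file via load_blocklist).
DEFAULT_COMMON_GROUPS = frozenset(
    {
        "HOH", "DOD", "WAT",
        "SO4", "PO4", "GOL", "EDO", "PEG", "ACT", "DMS",
        "FMT", "MPD", "TRS", "CIT", "NO3", "CL", "BR", "IOD",
    }
)


def load_blocklist(path) -> frozenset:
    """Read a one-component-ID-per-line blocklist file."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            ids.add(line)
    return frozenset(ids)


class CellGrid:
    """Spatial hash of heavy atoms into cubic cells of edge ``cell_size``.

    An atom at position p lives in cell ``floor(p / cell_size)`` per
    axis, so any pair within ``cell_size`` of each other is found by
    scanning the 3x3x3 neighbourhood of the query cell.
    """

    __slots__ = ("cell_size", "occupancy")

    def __init__(self, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = cell_size
        # cell coordinate triple -> list of (group index, x, y, z)
        self.occupancy: dict = defaultdict(list)

    def _cell(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        s = self.cell_size
        return (floor(x / s), floor(y / s), floor(z / s))

    def insert(self, group_index: int, x: float, y: float, z: float) -> None:
        self.occupancy[self._cell(x, y, z)].append((group_index, x, y, z))

    def neighbourhood(self, x: float, y: float, z: float) -> Iterable:
        """All stored atoms in the 27 cells around the query position."""
        cx, cy, cz = self._cell(x, y, z)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    cell = self.occupancy.get((cx + dx, cy + dy, cz + dz))
                    if cell:
                        yield from cell

    @classmethod
    def from_groups(
        cls, entry: StructureEntry, groups: Iterable[int], cell_size: float
    ) -> "CellGrid":
        grid = cls(cell_size)
        for gi in groups:
            for _, atom in entry.groups[gi].heavy_atoms():
                grid.insert(gi, atom.x, atom.y, atom.z)
        return grid


def prune_identical_groups(entry: StructureEntry, sel: SelectionSet) -> SelectionSet:
    """Collapse biologically identical groups across assembly copies.

    Groups in the selection sharing ``(name, seq_id)`` whose chains lie
    in different biological-assembly copies are redundant views of one
    entity; only the lowest group index of such a class is kept.
    Classes confined to a single copy label (including all-unlabelled
    chains) are left untouched, as are groups with distinct
    ``(name, seq_id)``.
    """
    by_class: dict = defaultdict(list)
    for gi in sel.indices:
        g = entry.groups[gi]
        by_class[(g.name, g.seq_id)].append(gi)

    kept = []
    for members in by_class.values():
        labels = {
            entry.chain_assembly_label(entry.groups[gi].chain_index)
            for gi in members
        }
        if len(members) > 1 and len(labels) > 1:
            kept.append(min(members))
        else:
            kept.extend(members)
    return SelectionSet(sel.entry_id, tuple(sorted(kept)))


def prune_common_groups(
    entry: StructureEntry,
    sel: SelectionSet,
    blocklist: frozenset = DEFAULT_COMMON_GROUPS,
) -> SelectionSet:
    """Drop groups whose component ID is on the blocklist."""
    indices = tuple(
        gi for gi in sel.indices if entry.groups[gi].name not in blocklist
    )
    return SelectionSet(sel.entry_id, indices)


def keep_interactions(
    entry: StructureEntry,
    sel: SelectionSet,
    against: SelectionSet,
    cutoff: float,
    mode: str = "keep",
) -> SelectionSet:
    """Filter ``sel`` by spatial proximity to ``against``.

    ``mode="keep"`` keeps every group of ``sel`` with a heavy atom
    within ``cutoff`` Å (closed comparison) of a heavy atom of some
    *other* group in ``against``; ``mode="remove"`` returns the
    complement within ``sel``.  A group never interacts with itself,
    so selections may overlap.
    """
    if cutoff <= 0:
        raise StructmineError(f"cutoff must be positive, got {cutoff}")
    if mode not in ("keep", "remove"):
        raise StructmineError(f"mode must be 'keep' or 'remove', got {mode!r}")
    if sel.entry_id != against.entry_id:
        raise StructmineError(
            f"selections from different entries: {sel.entry_id!r} vs "
            f"{against.entry_id!r}"
        )

    against_atoms = any(
        True
        for gi in against.indices
        for _ in entry.groups[gi].heavy_atoms()
    )
    if not against_atoms:
        interacting: set = set()
    else:
        grid = CellGrid.from_groups(entry, against.indices, cutoff)
        cutoff_sq = cutoff * cutoff
        interacting = set()
        for gi in sel.indices:
            found = False
            for _, atom in entry.groups[gi].heavy_atoms():
                for other_gi, x, y, z in grid.neighbourhood(atom.x, atom.y, atom.z):
                    if other_gi == gi:
                        continue
                    dx = atom.x - x
                    dy = atom.y - y
                    dz = atom.z - z
                    if dx * dx + dy * dy + dz * dz <= cutoff_sq:
                        found = True
                        break
                if found:
                    break
            if found:
                interacting.add(gi)

    if mode == "keep":
        indices = tuple(gi for gi in sel.indices if gi in interacting)
    else:
        indices = tuple(gi for gi in sel.indices if gi not in interacting)
    return SelectionSet(sel.entry_id, indices)
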