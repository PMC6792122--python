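"""Stage-1 selectors: build SelectionSets by group size and composition.

Selection works at the group level, querying each group's heavy-atom
count and its mmCIF ``chem_comp.type`` classification.  A group is
*non-polymer* when its composition type contains ``NON-POLYMER`` or
``SACCHARIDE``, or when the type is empty and the group sits in a chain
with no polymer-linking groups.  Waters (HOH/DOD/WAT) are excluded from
small-molecule selection unconditionally.

All selectors are pure: the entry is never mutated and the same entry
plus config always yields the same selection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .model import Group, SelectionSet, StructureEntry, group_heavy_atom_count

__all__ = [
    "SelectorConfig",
    "WATER_NAMES",
    "DEFAULT_METAL_ELEMENTS",
    "is_water",
    "is_non_polymer",
    "select_small_molecules",
    "select_metal_ions",
    "select_peptides",
    "select_nucleic_acids",
    "select_by_name",
]

#: Chemical-component IDs treated as water.
WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})

#: PDB-common metals; overridable via SelectorConfig.metal_elements.
DEFAULT_METAL_ELEMENTS = frozenset(
    {
        "LI", "NA", "K", "RB", "CS",
        "BE", "MG", "CA", "SR", "BA",
        "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG",
        "AL", "GA", "PB", "AG", "AU", "PT", "PD",
        "V", "CR", "MO", "W", "TL",
    }
)

DEFAULT_PEPTIDE_TYPES = frozenset(
    {"L-PEPTIDE LINKING", "D-PEPTIDE LINKING", "PEPTIDE LINKING"}
)
DEFAULT_NUCLEIC_TYPES = frozenset(
    {"DNA LINKING", "RNA LINKING", "L-DNA LINKING", "L-RNA LINKING"}
)


@dataclass(frozen=True)
class SelectorConfig:
    """Thresholds and classification sets for the group selectors.

    ``min_heavy_atoms``/``max_heavy_atoms`` bound the small-molecule
    size window (defaults 8–200 heavy atoms: large enough to drop most
    crystallisation additives, small enough to keep real ligands).
    """

    min_heavy_atoms: int = 8
    max_heavy_atoms: int = 200
    metal_elements: frozenset = DEFAULT_METAL_ELEMENTS
    peptide_comp_types: frozenset = DEFAULT_PEPTIDE_TYPES
    nucleic_comp_types: frozenset = DEFAULT_NUCLEIC_TYPES

    def __post_init__(self) -> None:
        if self.min_heavy_atoms < 1:
            raise ValueError("min_heavy_atoms must be >= 1")
        if self.min_heavy_atoms > self.max_heavy_atoms:
            raise ValueError("min_heavy_atoms must not exceed max_heavy_atoms")

    @classmethod
    def from_file(cls, path) -> "SelectorConfig":
        """Load overrides from a plain-text ``key = value`` file.

        Set-valued keys take comma-separated lists; unknown keys are an
        error so typos do not silently fall back to defaults.
        """
        cfg = cls()
        overrides = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("min_heavy_atoms", "max_heavy_atoms"):
                overrides[key] = int(value)
            elif key in ("metal_elements", "peptide_comp_types", "nucleic_comp_types"):
                overrides[key] = frozenset(
                    v.strip().upper() for v in value.split(",") if v.strip()
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        return replace(cfg, **overrides)


def is_water(group: Group) -> bool:
    return group.name in WATER_NAMES


def _polymer_chains(entry: StructureEntry) -> frozenset:
    """Chains containing at least one polymer-linking group."""
    return frozenset(
        g.chain_index for g in entry.groups if "LINKING" in g.comp_type
    )


def is_non_polymer(entry: StructureEntry, group: Group) -> bool:
    """Whether a group belongs to the non-polymer (ligand/ion/solvent) class."""
    ct = group.comp_type
    if "NON-POLYMER" in ct or "SACCHARIDE" in ct:
        return True
    if ct == "":
        return group.chain_index not in _polymer_chains(entry)
    return False


def select_small_molecules(
    entry: StructureEntry, cfg: SelectorConfig = SelectorConfig()
) -> SelectionSet:
    """Non-polymer, non-water groups within the heavy-atom size window."""
    indices = [
        i
        for i, g in enumerate(entry.groups)
        if is_non_polymer(entry, g)
        and not is_water(g)
        and cfg.min_heavy_atoms <= group_heavy_atom_count(g) <= cfg.max_heavy_atoms
    ]
    return SelectionSet(entry.pdb_id, tuple(indices))


def select_metal_ions(
    entry: StructureEntry, cfg: SelectorConfig = SelectorConfig()
) -> SelectionSet:
    """Single-heavy-atom non-polymer groups whose lone heavy atom is a metal.

    Multi-atom groups containing a metal centre (e.g. a heme) are
    deliberately excluded: they are ligands, not free ions.
    """
    indices = []
    for i, g in enumerate(entry.groups):
        if not is_non_polymer(entry, g):
            continue
        heavy = [atom for _, atom in g.heavy_atoms()]
        if len(heavy) == 1 and heavy[0].element in cfg.metal_elements:
            indices.append(i)
    return SelectionSet(entry.pdb_id, tuple(indices))


def select_peptides(
    entry: StructureEntry, cfg: SelectorConfig = SelectorConfig()
) -> SelectionSet:
    indices = [
        i for i, g in enumerate(entry.groups) if g.comp_type in cfg.peptide_comp_types
    ]
    return SelectionSet(entry.pdb_id, tuple(indices))


def select_nucleic_acids(
    entry: StructureEntry, cfg: SelectorConfig = SelectorConfig()
) -> SelectionSet:
    indices = [
        i for i, g in enumerate(entry.groups) if g.comp_type in cfg.nucleic_comp_types
    ]
    return SelectionSet(entry.pdb_id, tuple(indices))


def select_by_name(entry: StructureEntry, names: set) -> SelectionSet:
    """Groups whose chemical-component ID is in ``names`` (uppercase)."""
    wanted = frozenset(names)
    indices = [i for i, g in enumerate(entry.groups) if g.name in wanted]
    return SelectionSet(entry.pdb_id, tuple(indices))
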