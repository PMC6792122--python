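"""Synthetic structure corpora: parameterised entries encoded to MMTF
and packed into Hadoop sequence-file shards.

Every module in this package is testable offline against corpora built
here.  An entry contains, per biological-assembly copy:

* poly-alanine/glycine protein chains laid on an ideal helix with
  3.8 Å Cα–Cα spacing (backbone N, CA, C, O plus CB on alanine);
* ligands built as connected random-walk graphs of C/N/O heavy atoms
  with bond lengths in 1.3–1.6 Å, placed so their minimum heavy-atom
  distance to the protein is ``ligand_offset`` Å;
* free metal ions placed at the same controlled offset;
* waters scattered at least 2.5 Å from everything else.

Assembly copies are rigid translated duplicates whose chains carry
canonical copy labels (``"1.0"``, ``"1.1"``, ...) in the assembly map.
Coordinates are pre-quantised to 1/1000 Å so every generated entry
round-trips bit-exactly through the MMTF codec.  Generation is
deterministic: each entry draws from its own seeded random stream
(corpus seed XOR entry ordinal), so corpora are reproducible under any
generation order.

Entry IDs are synthetic (``T000``, ``T001``, ...) and do not resolve
against the RCSB.  A ground-truth log records, per entry, every
group's role and heavy-atom count plus all pairwise group contacts
under 10 Å, for oracle tests against the selectors and pruners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from .hadoop_io import SequenceRecord, ShardManifest, write_sequence_file
from .mmtf_codec import dequantize, encode_entry, quantize
from .model import Atom, Group, StructmineError, StructureEntry

__all__ = [
    "GenerationError",
    "FixtureSpec",
    "EntryTruth",
    "CorpusTruth",
    "make_entry",
    "entry_ground_truth",
    "make_corpus",
    "write_ground_truth",
    "read_ground_truth",
]

HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TURN = math.radians(100.0)  # per residue
CONTACT_TRUTH_CUTOFF = 10.0  # Å; contacts below this are logged
COPY_SPACING = 80.0  # Å between assembly copies
CHAIN_SPACING = 16.0  # Å between peptide chains

_METAL_CYCLE = ("ZN", "NA", "MG", "K", "FE", "CU")


class GenerationError(StructmineError):
    """Packing failed after bounded retries (density too high)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic entry; the seed fixes it bit-exactly."""

    n_chains: int = 1
    residues_per_chain: int = 20
    n_ligands: int = 1
    ligand_heavy_atoms: int = 12
    n_waters: int = 10
    n_metals: int = 1
    n_assembly_copies: int = 1
    ligand_offset: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chains",
            "residues_per_chain",
            "n_ligands",
            "ligand_heavy_atoms",
            "n_waters",
            "n_metals",
            "n_assembly_copies",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_assembly_copies < 1:
            raise ValueError("n_assembly_copies must be >= 1")


def _q(value: float) -> float:
    """Quantise to 1/1000 Å so MMTF round trips are exact."""
    return dequantize(quantize(value))


def _make_atom(name: str, element: str, pos, charge: int = 0) -> Atom:
    return Atom(
        name=name,
        element=element,
        formal_charge=charge,
        x=_q(float(pos[0])),
        y=_q(float(pos[1])),
        z=_q(float(pos[2])),
    )


def _peptide_chain(
    chain_index: int,
    n_residues: int,
    origin: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 0.25,
) -> tuple:
    """One helical poly-ALA/GLY chain; returns (groups, inter_bond_stubs)
    where stubs are (local_group_i, atom_i, local_group_j, atom_j).

    Each residue is displaced by isotropic gaussian noise (σ =
    ``jitter`` Å) so entries differ in conformation, not just in
    ligand placement — without it every protein trace would be the
    same ideal helix and alignment RMSDs would all be zero."""
    groups = []
    stubs = []
    for r in range(n_residues):
        theta = HELIX_TURN * r
        ca = origin + np.array(
            [HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), HELIX_RISE * r]
        ) + rng.normal(0.0, jitter, size=3)
        is_ala = r % 2 == 0
        atoms = [
            _make_atom("N", "N", ca + (-0.8, -0.9, -0.6)),
            _make_atom("CA", "C", ca),
            _make_atom("C", "C", ca + (0.9, 0.8, 0.5)),
            _make_atom("O", "O", ca + (1.2, 0.3, 1.5)),
        ]
        bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 2)]
        if is_ala:
            atoms.append(_make_atom("CB", "C", ca + (0.6, -1.2, 0.4)))
            bonds.append((1, 4, 1))
        groups.append(
            Group(
                name="ALA" if is_ala else "GLY",
                comp_type="L-PEPTIDE LINKING",
                seq_id=r + 1,
                chain_index=chain_index,
                atoms=tuple(atoms),
                bonds=tuple(bonds),
            )
        )
        if r > 0:
            stubs.append((r - 1, 2, r, 0))  # C(i) - N(i+1)
    return groups, stubs


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            return v / norm


def _ligand_graph(rng: np.random.Generator, n_heavy: int) -> tuple:
    """Connected random-walk molecule around the origin; returns
    (positions, elements, bonds)."""
    positions = [np.zeros(3)]
    elements = ["C"]
    bonds = []
    for a in range(1, n_heavy):
        placed = False
        for _attempt in range(80):
            parent = int(rng.integers(0, a))
            pos = positions[parent] + _random_unit(rng) * rng.uniform(1.3, 1.6)
            clashing = any(
                i != parent and np.linalg.norm(pos - p) < 1.0
                for i, p in enumerate(positions)
            )
            if not clashing:
                positions.append(pos)
                elements.append(str(rng.choice(["C", "C", "C", "N", "O"])))
                lo, hi = min(parent, a), max(parent, a)
                bonds.append((lo, hi, 1))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place ligand atom {a} without clashes after 80 tries"
            )
    return positions, elements, bonds


def _min_dist_to(cloud: np.ndarray, points: np.ndarray) -> float:
    diff = cloud[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2).min()))


def _place_at_offset(
    rng: np.random.Generator,
    protein_atoms: np.ndarray,
    shape: np.ndarray,
    offset: float,
) -> np.ndarray:
    """Translate ``shape`` (centred positions) along a random direction
    so its minimum heavy-atom distance to the protein is ~``offset`` Å.

    Solved by bisection on the translation distance t: at
    ``t_hi = R_protein + R_shape + offset + 1`` the separation exceeds
    ``offset`` by construction (triangle inequality), so a bracket
    always exists unless the ray is already farther than ``offset`` at
    the centroid, in which case the centroid placement is kept (the
    ground-truth log records actual distances either way)."""
    centroid = protein_atoms.mean(axis=0)
    direction = _random_unit(rng)
    radius = float(np.linalg.norm(protein_atoms - centroid, axis=1).max())
    shape_radius = float(np.linalg.norm(shape, axis=1).max()) if len(shape) else 0.0

    def separation(t: float) -> float:
        return _min_dist_to(protein_atoms, shape + centroid + direction * t)

    lo, hi = 0.0, radius + shape_radius + offset + 1.0
    if separation(lo) >= offset:
        return shape + centroid
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if separation(mid) < offset:
            lo = mid
        else:
            hi = mid
    return shape + centroid + direction * hi


def make_entry(spec: FixtureSpec, pdb_id: str) -> StructureEntry:
    """Build one deterministic synthetic entry from its spec.

    Group order: per assembly copy, peptide chains, then ligands (one
    chain each), metals (one chain each), then one chain of waters.
    """
    rng = np.random.default_rng(spec.seed)

    copy0_groups: list[Group] = []
    copy0_chains: list[str] = []
    inter_bonds: list = []

    def next_chain(label: str) -> int:
        copy0_chains.append(label)
        return len(copy0_chains) - 1

    # protein chains
    protein_points = []
    for c in range(spec.n_chains):
        chain_index = next_chain(chr(ord("A") + c % 26))
        origin = np.array([c * CHAIN_SPACING, 0.0, 0.0])
        groups, stubs = _peptide_chain(chain_index, spec.residues_per_chain, origin, rng)
        base = len(copy0_groups)
        copy0_groups.extend(groups)
        for gi, ai, gj, aj in stubs:
            inter_bonds.append(((base + gi, ai), (base + gj, aj), 1))
        for g in groups:
            for atom in g.atoms:
                protein_points.append((atom.x, atom.y, atom.z))
    protein_atoms = (
        np.array(protein_points) if protein_points else np.zeros((1, 3))
    )

    occupied = [protein_atoms] if protein_points else []

    # ligands
    for li in range(spec.n_ligands):
        if spec.ligand_heavy_atoms == 0:
            continue
        chain_index = next_chain(f"L{li}")
        positions, elements, bonds = _ligand_graph(rng, spec.ligand_heavy_atoms)
        shape = np.array(positions) - np.array(positions).mean(axis=0)
        placed = _place_at_offset(rng, protein_atoms, shape, spec.ligand_offset + li * 2.0)
        atoms = tuple(
            _make_atom(f"{el}{i + 1}", el, placed[i]) for i, el in enumerate(elements)
        )
        copy0_groups.append(
            Group(
                name=f"LG{li}" if li < 10 else f"L{li:02d}",
                comp_type="NON-POLYMER",
                seq_id=401 + li,
                chain_index=chain_index,
                atoms=atoms,
                bonds=tuple(bonds),
            )
        )
        occupied.append(placed)

    # metal ions
    for mi in range(spec.n_metals):
        chain_index = next_chain(f"M{mi}")
        element = _METAL_CYCLE[mi % len(_METAL_CYCLE)]
        point = _place_at_offset(
            rng, protein_atoms, np.zeros((1, 3)), spec.ligand_offset + 1.0 + mi
        )
        copy0_groups.append(
            Group(
                name=element,
                comp_type="NON-POLYMER",
                seq_id=501 + mi,
                chain_index=chain_index,
                atoms=(_make_atom(element, element, point[0], charge=2 if element != "NA" and element != "K" else 1),),
            )
        )
        occupied.append(point)

    # waters, all on one chain
    if spec.n_waters:
        chain_index = next_chain("W")
        lo = protein_atoms.min(axis=0) - 8.0
        hi = protein_atoms.max(axis=0) + 8.0
        placed_waters = []
        for wi in range(spec.n_waters):
            ok = False
            for _attempt in range(300):
                pos = rng.uniform(lo, hi)
                clouds = occupied + (
                    [np.array(placed_waters)] if placed_waters else []
                )
                if all(_min_dist_to(cloud, pos[None, :]) >= 2.5 for cloud in clouds):
                    ok = True
                    break
            if not ok:
                raise GenerationError(
                    f"could not place water {wi} with 2.5 Å spacing after 300 tries"
                )
            placed_waters.append(pos)
            copy0_groups.append(
                Group(
                    name="HOH",
                    comp_type="NON-POLYMER",
                    seq_id=601 + wi,
                    chain_index=chain_index,
                    atoms=(_make_atom("O", "O", pos),),
                )
            )

    # replicate assembly copies as rigid translated duplicates
    groups: list[Group] = []
    chain_ids: list[str] = []
    assembly_map: list[str] = []
    all_inter: list = []
    n_copy_chains = len(copy0_chains)
    n_copy_groups = len(copy0_groups)
    for copy in range(spec.n_assembly_copies):
        shift = np.array([0.0, 0.0, copy * COPY_SPACING])
        label = f"1.{copy}" if spec.n_assembly_copies > 1 else ""
        for cid in copy0_chains:
            # copies reuse the chain names, as real assemblies do
            chain_ids.append(cid)
            assembly_map.append(label)
        for g in copy0_groups:
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element,
                    formal_charge=a.formal_charge,
                    x=_q(a.x + shift[0]),
                    y=_q(a.y + shift[1]),
                    z=_q(a.z + shift[2]),
                )
                for a in g.atoms
            )
            groups.append(
                Group(
                    name=g.name,
                    comp_type=g.comp_type,
                    seq_id=g.seq_id,
                    chain_index=g.chain_index + copy * n_copy_chains,
                    atoms=atoms,
                    bonds=g.bonds,
                )
            )
        for (gi, ai), (gj, aj), order in inter_bonds:
            all_inter.append(
                ((gi + copy * n_copy_groups, ai), (gj + copy * n_copy_groups, aj), order)
            )

    return StructureEntry(
        pdb_id=pdb_id.upper(),
        groups=tuple(groups),
        chain_ids=tuple(chain_ids),
        inter_group_bonds=tuple(all_inter),
        assembly_map=tuple(assembly_map),
    )


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

_ROLE_BY_NAME = {"ALA": "peptide", "GLY": "peptide", "HOH": "water"}


def _group_role(name: str) -> str:
    if name in _ROLE_BY_NAME:
        return _ROLE_BY_NAME[name]
    if name in _METAL_CYCLE:
        return "metal"
    return "ligand"


@dataclass(frozen=True)
class EntryTruth:
    """Generator-side facts about one entry: per-group roles and
    heavy-atom counts, and all group-pair contacts under 10 Å."""

    pdb_id: str
    roles: dict  # group index -> (role, name, heavy atom count)
    contacts: dict  # (gi, gj) with gi < gj -> min heavy-atom distance


@dataclass
class CorpusTruth:
    entries: dict = field(default_factory=dict)  # pdb_id -> EntryTruth


def entry_ground_truth(entry: StructureEntry) -> EntryTruth:
    """Roles from the generator's naming conventions; contacts by
    brute-force minimum heavy-atom distance over all group pairs."""
    roles = {}
    clouds = []
    for gi, g in enumerate(entry.groups):
        heavy = np.array([(a.x, a.y, a.z) for a in g.atoms if a.is_heavy])
        roles[gi] = (_group_role(g.name), g.name, len(heavy))
        clouds.append(heavy)
    contacts = {}
    n = len(clouds)
    for gi in range(n):
        if clouds[gi].size == 0:
            continue
        for gj in range(gi + 1, n):
            if clouds[gj].size == 0:
                continue
            d = _min_dist_to(clouds[gi], clouds[gj])
            if d < CONTACT_TRUTH_CUTOFF:
                contacts[(gi, gj)] = d
    return EntryTruth(pdb_id=entry.pdb_id, roles=roles, contacts=contacts)


def write_ground_truth(truth: CorpusTruth, path) -> None:
    """Tab-separated log: one 'group' row per group, one 'contact' row
    per sub-10 Å pair."""
    lines = []
    for pdb_id in sorted(truth.entries):
        et = truth.entries[pdb_id]
        for gi in sorted(et.roles):
            role, name, heavy = et.roles[gi]
            lines.append(f"group\t{pdb_id}\t{gi}\t{role}\t{name}\t{heavy}")
        for (gi, gj), d in sorted(et.contacts.items()):
            lines.append(f"contact\t{pdb_id}\t{gi}\t{gj}\t{d:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path) -> CorpusTruth:
    truth = CorpusTruth()
    roles: dict = {}
    contacts: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        kind, pdb_id = parts[0], parts[1]
        roles.setdefault(pdb_id, {})
        contacts.setdefault(pdb_id, {})
        if kind == "group":
            roles[pdb_id][int(parts[2])] = (parts[3], parts[4], int(parts[5]))
        elif kind == "contact":
            contacts[pdb_id][(int(parts[2]), int(parts[3]))] = float(parts[4])
    for pdb_id in roles:
        truth.entries[pdb_id] = EntryTruth(
            pdb_id=pdb_id, roles=roles[pdb_id], contacts=contacts[pdb_id]
        )
    return truth


# --------------------------------------------------------------------------
# corpora
# --------------------------------------------------------------------------


def _entry_spec(base: FixtureSpec, rng: np.random.Generator, seed: int) -> FixtureSpec:
    """Per-entry variation around the base spec: ligand sizes straddle
    the default small-molecule window so selector tests exercise both
    sides of the size threshold."""
    lig = int(
        rng.integers(
            max(4, base.ligand_heavy_atoms - 6), base.ligand_heavy_atoms + 5
        )
    )
    waters = int(rng.integers(max(0, base.n_waters - 4), base.n_waters + 5))
    return replace(base, ligand_heavy_atoms=lig, n_waters=waters, seed=seed)


def make_corpus(
    n_entries: int,
    n_shards: int,
    base_spec: FixtureSpec = FixtureSpec(),
    seed: int = 0,
    out_dir=None,
    vary: bool = True,
) -> tuple[ShardManifest, CorpusTruth]:
    """Generate a corpus: entries round-robin across shards, plus the
    ground-truth log (written alongside the shards as truth.tsv when
    ``out_dir`` is given).

    Entry ``i`` gets PDB ID ``T{i:03d}`` and its own random stream
    seeded with ``seed XOR i``, so any shard can be regenerated
    independently.  ``vary=False`` pins every entry to ``base_spec``
    exactly (only geometry varies with the stream).
    """
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    shards: list[list[SequenceRecord]] = [[] for _ in range(n_shards)]
    truth = CorpusTruth()
    for i in range(n_entries):
        entry_seed = (seed ^ i) & 0x7FFFFFFF
        meta_rng = np.random.default_rng((entry_seed * 2654435761 + 1) & 0x7FFFFFFF)
        spec = (
            _entry_spec(base_spec, meta_rng, entry_seed)
            if vary
            else replace(base_spec, seed=entry_seed)
        )
        pdb_id = f"T{i:03d}"
        entry = make_entry(spec, pdb_id)
        truth.entries[pdb_id] = entry_ground_truth(entry)
        shards[i % n_shards].append(
            SequenceRecord(key=pdb_id.encode(), value=encode_entry(entry))
        )

    paths = []
    for s, records in enumerate(shards):
        path = out_dir / f"full_{s}.hadoop"
        write_sequence_file(path, records)
        paths.append(path)
    write_ground_truth(truth, out_dir / "truth.tsv")
    return ShardManifest(paths), truth
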