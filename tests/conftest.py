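"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from structmine.fixtures import FixtureSpec, make_corpus, make_entry
from structmine.model import Atom, Group, StructureEntry

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def atom(name: str, element: str, x: float, y: float, z: float, charge: int = 0) -> Atom:
    return Atom(name=name, element=element, formal_charge=charge, x=x, y=y, z=z)


def simple_group(
    name: str,
    comp_type: str,
    atoms,
    seq_id: int = 1,
    chain_index: int = 0,
    bonds=(),
) -> Group:
    return Group(
        name=name,
        comp_type=comp_type,
        seq_id=seq_id,
        chain_index=chain_index,
        atoms=tuple(atoms),
        bonds=tuple(bonds),
    )


def entry_of(groups, pdb_id: str = "TEST", n_chains: int | None = None,
             inter_group_bonds=(), assembly_map=()) -> StructureEntry:
    if n_chains is None:
        n_chains = max((g.chain_index for g in groups), default=-1) + 1
    return StructureEntry(
        pdb_id=pdb_id,
        groups=tuple(groups),
        chain_ids=tuple(chr(ord("A") + i) for i in range(n_chains)),
        inter_group_bonds=tuple(inter_group_bonds),
        assembly_map=tuple(assembly_map),
    )


def fixture_entry(seed: int, **overrides) -> StructureEntry:
    """A generated entry with a given stream seed."""
    spec = FixtureSpec(**{"seed": seed, **overrides})
    return make_entry(spec, f"T{seed % 1000:03d}")


def brute_force_interacting(entry, sel, against, cutoff):
    """O(n^2) all-pairs oracle for keep_interactions: the set of groups
    in sel with a heavy atom within cutoff of a heavy atom of any
    *other* group in against."""
    coords = {}
    for gi in set(sel.indices) | set(against.indices):
        pts = np.array(
            [(a.x, a.y, a.z) for a in entry.groups[gi].atoms if a.is_heavy]
        )
        coords[gi] = pts
    hits = set()
    for gi in sel.indices:
        if coords[gi].size == 0:
            continue
        for gj in against.indices:
            if gj == gi or coords[gj].size == 0:
                continue
            diff = coords[gi][:, None, :] - coords[gj][None, :, :]
            if (diff * diff).sum(axis=2).min() <= cutoff * cutoff:
                hits.add(gi)
                break
    return hits


def quaternion_superpose_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """SVD-free superposition oracle: Horn's closed-form quaternion
    method.  The optimal rotation's quality is the largest eigenvalue
    of a 4x4 symmetric matrix built from the correlation of the two
    centred point sets."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    s = mov_c.T @ ref_c
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n_mat = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(n_mat).max())
    n = ref.shape[0]
    sq = (ref_c**2).sum() + (mov_c**2).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / n))


@pytest.fixture(scope="session")
def session_corpus(tmp_path_factory):
    """A 100-entry, 20-shard corpus shared by engine and workflow
    tests; generation is deterministic, so sharing is safe."""
    out = tmp_path_factory.mktemp("corpus")
    manifest, truth = make_corpus(
        100, 20, base_spec=FixtureSpec(), seed=11, out_dir=out
    )
    return manifest, truth
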