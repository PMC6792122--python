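"""Stage-3 calculators: features computed from pruned selections.

* :func:`count_group_names` — multiset counts of component IDs;
* :func:`min_group_distance` — minimum heavy-atom distance between two
  groups;
* :func:`bond_geometry` — binned bond-length and bond-angle histograms
  over every bond whose endpoints lie inside the selection;
* :func:`kabsch_superpose` — least-squares optimal rigid superposition
  (proper rotation + translation) of two ordered point sets, with the
  reflection case resolved by sign-flipping the smallest singular
  direction;
* :func:`alpha_carbon_trace` — ordered Cα coordinates feeding the
  superposition for protein alignment.

Histogram bins are left-closed: bond lengths in 0.01 Å bins
``[k·0.01, (k+1)·0.01)``, angles in 1° bins ``[k, k+1)``.  Element
labels in histogram keys are canonical — pairs sorted, triples with
the centre element fixed in the middle and the flanks sorted — so
histograms from different entries merge cleanly.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import SelectionSet, StructmineError, StructureEntry

__all__ = [
    "UndefinedDistanceError",
    "DegeneracyError",
    "GeometryStats",
    "Superposition",
    "min_group_distance",
    "bond_geometry",
    "kabsch_superpose",
    "alpha_carbon_trace",
    "count_group_names",
]

BOND_BIN_WIDTH = 0.01  # Å
ANGLE_BIN_WIDTH = 1.0  # degrees


class UndefinedDistanceError(StructmineError):
    """A group distance was requested for a group with no heavy atoms."""


class DegeneracyError(StructmineError):
    """Input too degenerate for a unique superposition (collinear or
    coincident points, or too few of them)."""


def bond_bin(distance: float) -> float:
    """Lower edge of the 0.01 Å bin containing ``distance``."""
    return math.floor(distance / BOND_BIN_WIDTH) * BOND_BIN_WIDTH


def angle_bin(angle_deg: float) -> float:
    """Lower edge of the 1° bin containing ``angle_deg``."""
    return math.floor(angle_deg / ANGLE_BIN_WIDTH) * ANGLE_BIN_WIDTH


def bond_key(element_a: str, element_b: str) -> tuple[str, str]:
    """Canonical (sorted) element pair."""
    return (element_a, element_b) if element_a <= element_b else (element_b, element_a)


def angle_key(flank_a: str, center: str, flank_b: str) -> tuple[str, str, str]:
    """Canonical element triple: centre fixed in the middle, flanks sorted."""
    lo, hi = (flank_a, flank_b) if flank_a <= flank_b else (flank_b, flank_a)
    return (lo, center, hi)


@dataclass
class GeometryStats:
    """Binned bond-length and bond-angle histograms.

    ``bond_length_hist`` maps ``(element pair, bin lower edge)`` to a
    count, ``angle_hist`` maps ``(element triple, bin lower edge)``.
    The histograms are mergeable across entries via :meth:`merge`.
    """

    bond_length_hist: dict = field(default_factory=dict)
    angle_hist: dict = field(default_factory=dict)
    n_bonds: int = 0
    n_angles: int = 0

    def add_bond(self, key: tuple[str, str], distance: float) -> None:
        edge = bond_bin(distance)
        self.bond_length_hist[(key, edge)] = (
            self.bond_length_hist.get((key, edge), 0) + 1
        )
        self.n_bonds += 1

    def add_angle(self, key: tuple[str, str, str], angle_deg: float) -> None:
        edge = angle_bin(angle_deg)
        self.angle_hist[(key, edge)] = self.angle_hist.get((key, edge), 0) + 1
        self.n_angles += 1

    def merge(self, other: "GeometryStats") -> "GeometryStats":
        merged = GeometryStats(
            bond_length_hist=dict(self.bond_length_hist),
            angle_hist=dict(self.angle_hist),
            n_bonds=self.n_bonds + other.n_bonds,
            n_angles=self.n_angles + other.n_angles,
        )
        for k, v in other.bond_length_hist.items():
            merged.bond_length_hist[k] = merged.bond_length_hist.get(k, 0) + v
        for k, v in other.angle_hist.items():
            merged.angle_hist[k] = merged.angle_hist.get(k, 0) + v
        return merged

    def to_rows(self) -> list[tuple[str, str, str, str]]:
        """Tab-separated-ready rows: kind, element key, bin edge, count."""
        rows = []
        for (elements, edge), count in self.bond_length_hist.items():
            rows.append(("bond", "-".join(elements), f"{edge:.2f}", str(count)))
        for (elements, edge), count in self.angle_hist.items():
            rows.append(("angle", "-".join(elements), f"{edge:.0f}", str(count)))
        return sorted(rows)

    def to_tsv(self) -> str:
        return "\n".join("\t".join(row) for row in self.to_rows())


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping a moving set onto a reference:
    ``ref ≈ rotation @ mov + translation``."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_points: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def min_group_distance(entry: StructureEntry, g1: int, g2: int) -> float:
    """Minimum euclidean distance over heavy-atom pairs of two groups."""
    if g1 == g2:
        raise StructmineError("min_group_distance requires two distinct groups")
    a = np.array(
        [(atom.x, atom.y, atom.z) for _, atom in entry.groups[g1].heavy_atoms()]
    )
    b = np.array(
        [(atom.x, atom.y, atom.z) for _, atom in entry.groups[g2].heavy_atoms()]
    )
    if a.size == 0 or b.size == 0:
        raise UndefinedDistanceError(
            f"group {g1 if a.size == 0 else g2} of {entry.pdb_id} has no heavy atoms"
        )
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2).min()))


def _selected_bonds(entry: StructureEntry, sel: SelectionSet):
    """All bonds with both endpoints inside selected groups, as
    ((group, atom), (group, atom)) node pairs."""
    selected = set(sel.indices)
    for gi in sel.indices:
        for i, j, _order in entry.groups[gi].bonds:
            yield (gi, i), (gi, j)
    for (gi, ai), (gj, aj), _order in entry.inter_group_bonds:
        if gi in selected and gj in selected:
            yield (gi, ai), (gj, aj)


def bond_geometry(entry: StructureEntry, sel: SelectionSet) -> GeometryStats:
    """Bond-length and angle histograms over the selection.

    Lengths cover every intra-group bond of a selected group and every
    inter-group bond with both endpoints selected; angles cover every
    pair of such bonds sharing a common atom.  Angles at coincident
    atoms (zero-length arm) are skipped — they have no defined value.
    """
    stats = GeometryStats()
    positions: dict = {}
    elements: dict = {}
    adjacency: dict = defaultdict(list)

    def node_info(node):
        if node not in positions:
            gi, ai = node
            atom = entry.groups[gi].atoms[ai]
            positions[node] = np.array((atom.x, atom.y, atom.z))
            elements[node] = atom.element
        return positions[node], elements[node]

    for a, b in _selected_bonds(entry, sel):
        pa, ea = node_info(a)
        pb, eb = node_info(b)
        stats.add_bond(bond_key(ea, eb), float(np.linalg.norm(pa - pb)))
        adjacency[a].append(b)
        adjacency[b].append(a)

    for center, neighbours in adjacency.items():
        pc, ec = node_info(center)
        for i in range(len(neighbours)):
            for j in range(i + 1, len(neighbours)):
                u = positions[neighbours[i]] - pc
                v = positions[neighbours[j]] - pc
                nu, nv = np.linalg.norm(u), np.linalg.norm(v)
                if nu == 0.0 or nv == 0.0:
                    continue
                cos = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
                stats.add_angle(
                    angle_key(elements[neighbours[i]], ec, elements[neighbours[j]]),
                    math.degrees(math.acos(cos)),
                )
    return stats


def kabsch_superpose(
    ref: Sequence[Sequence[float]], mov: Sequence[Sequence[float]]
) -> Superposition:
    """Least-squares optimal rigid superposition of ``mov`` onto ``ref``.

    Both inputs are ordered N×3 point lists with 1:1 positional
    correspondence, N ≥ 3.  The rotation is proper (det +1): when the
    best orthogonal transform would be a reflection, the smallest
    singular direction is sign-flipped.  Raises
    :class:`DegeneracyError` for collinear or coincident inputs, where
    the rotation is not unique.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or mov.ndim != 2 or mov.shape[1] != 3:
        raise StructmineError("point sets must be N x 3")
    if ref.shape[0] != mov.shape[0]:
        raise StructmineError(
            f"point sets differ in length: {ref.shape[0]} vs {mov.shape[0]}"
        )
    n = ref.shape[0]
    if n < 3:
        raise StructmineError("superposition requires at least 3 points")

    ref_centroid = ref.mean(axis=0)
    mov_centroid = mov.mean(axis=0)
    ref_c = ref - ref_centroid
    mov_c = mov - mov_centroid

    spread = min(np.linalg.norm(ref_c, axis=1).max(), np.linalg.norm(mov_c, axis=1).max())
    if spread == 0.0:
        raise DegeneracyError("all points coincident; rotation undefined")

    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # Rank < 2 means the correlation leaves a rotation axis free.
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegeneracyError("points are collinear; rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref_centroid - rotation @ mov_centroid
    moved = mov_c @ rotation.T
    rmsd = float(np.sqrt(((moved - ref_c) ** 2).sum() / n))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd, n_points=n)


def alpha_carbon_trace(entry: StructureEntry, sel: SelectionSet) -> np.ndarray:
    """Cα coordinates of selected groups, in group order.

    Takes the first atom named ``CA`` with element C in each group
    (the element check keeps calcium ions, whose lone atom is also
    named CA, out of protein traces); groups without a Cα are skipped.
    Fewer than 3 Cα atoms raise :class:`DegeneracyError`.
    """
    points = []
    for gi in sel.indices:
        for atom in entry.groups[gi].atoms:
            if atom.name == "CA" and atom.element == "C":
                points.append((atom.x, atom.y, atom.z))
                break
    if len(points) < 3:
        raise DegeneracyError(
            f"{entry.pdb_id}: only {len(points)} CA atoms in selection; need >= 3"
        )
    return np.array(points)


def count_group_names(entry: StructureEntry, sel: SelectionSet) -> dict[str, int]:
    """Multiset counts of component IDs within the selection."""
    counts: dict[str, int] = {}
    for gi in sel.indices:
        name = entry.groups[gi].name
        counts[name] = counts.get(name, 0) + 1
    return counts
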