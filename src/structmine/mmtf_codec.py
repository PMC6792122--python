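"""MMTF (MacroMolecular Transmission Format) codec.

MMTF stores a structure as a msgpack map whose large numeric fields are
binary blobs with a 12-byte header — big-endian int32 codec id, element
count and codec parameter — followed by big-endian payload data.  The
per-field strategies implemented here are the ones real PDB MMTF v1.0
files use:

====  =========================================================
 id   strategy
====  =========================================================
  1   float32 pass-through
  2   int8 pass-through
  3   int16 pass-through
  4   int32 pass-through
  5   fixed-length UTF-8 string array (parameter = width)
  6   run-length encoded char array
  7   run-length encoded int32 array
  8   delta + run-length encoded int32 array
  9   run-length encoded int32, fixed-point (divide by parameter)
 10   delta + recursive-index int16, fixed-point
 11   int16, fixed-point
 12   recursive-index int16, fixed-point
 13   recursive-index int8, fixed-point
 14   recursive-index int16
 15   recursive-index int8
====  =========================================================

Any other id raises :class:`UnsupportedCodecError` rather than
misparsing.

:func:`decode_entry` turns a (optionally gzip-wrapped) MMTF blob into a
:class:`~structmine.model.StructureEntry`; :func:`encode_entry` is its
exact inverse, used to build synthetic corpora.  Decoding reads model 1
only, keeps the first-listed alternate location of each atom, and
derives per-chain biological-assembly copy labels of the form
``"<assembly name>.<transform index>"`` from ``bioAssemblyList``.
Coordinates are stored at 1/1000 Å (divisor 1000), B-factors at 1/100;
fixed-point quantisation rounds half away from zero, which makes
encode → decode bit-exact on pre-quantised coordinates.
"""

from __future__ import annotations

import gzip
import math
import struct
import zlib
from dataclasses import dataclass
from typing import Any, Sequence

import msgpack
import numpy as np

from .model import Atom, Group, StructmineError, StructureEntry

__all__ = [
    "CodecError",
    "DecodeError",
    "SchemaError",
    "UnsupportedCodecError",
    "EncodedField",
    "decode_numeric_array",
    "encode_numeric_array",
    "decode_entry",
    "encode_entry",
]

COORD_DIVISOR = 1000
BFACTOR_DIVISOR = 100

_GZIP_MAGIC = b"\x1f\x8b"
_INT16_MAX = 32767
_INT16_MIN = -32768
_INT8_MAX = 127
_INT8_MIN = -128


class CodecError(StructmineError):
    """Base class for MMTF encoding/decoding failures."""


class DecodeError(CodecError):
    """A blob could not be decompressed or unpacked."""


class SchemaError(CodecError):
    """A required MMTF field is missing or malformed."""


class UnsupportedCodecError(CodecError):
    """A binary field uses a codec strategy this reader does not implement."""


# --------------------------------------------------------------------------
# per-field binary codecs
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class EncodedField:
    """One binary-encoded MMTF field: strategy id, codec parameter and
    raw big-endian payload (header stripped)."""

    codec_id: int
    parameter: int
    payload: bytes

    @classmethod
    def from_bytes(cls, buf: bytes) -> "EncodedField":
        if len(buf) < 12:
            raise SchemaError(
                f"binary field too short for 12-byte header ({len(buf)} bytes)"
            )
        codec_id, _count, parameter = struct.unpack(">iii", buf[:12])
        return cls(codec_id, parameter, buf[12:])

    def to_bytes(self, count: int) -> bytes:
        return struct.pack(">iii", self.codec_id, count, self.parameter) + self.payload


def _ints(payload: bytes, dtype: str) -> np.ndarray:
    return np.frombuffer(payload, dtype=dtype).astype(np.int64)


def _run_length_decode(values: np.ndarray) -> np.ndarray:
    if values.size % 2:
        raise SchemaError("run-length payload has an odd number of int32 values")
    counts = values[1::2]
    if counts.size and counts.min() < 0:
        raise SchemaError("run-length count is negative")
    return np.repeat(values[0::2], counts)


def _run_length_encode(values: Sequence[int]) -> list[int]:
    out: list[int] = []
    for v in values:
        if out and out[-2] == v:
            out[-1] += 1
        else:
            out.extend((int(v), 1))
    return out


def _recursive_index_decode(values: np.ndarray, lo: int, hi: int) -> list[int]:
    out: list[int] = []
    acc = 0
    for v in values.tolist():
        acc += v
        if v != hi and v != lo:
            out.append(acc)
            acc = 0
    return out


def _recursive_index_encode(values: Sequence[int], lo: int, hi: int) -> list[int]:
    out: list[int] = []
    for v in values:
        v = int(v)
        while v > hi:
            out.append(hi)
            v -= hi
        while v < lo:
            out.append(lo)
            v -= lo
        out.append(v)
    return out


def _fixed_point(values: np.ndarray, divisor: int) -> np.ndarray:
    return values.astype(np.float64) / float(divisor)


def quantize(value: float, divisor: int = COORD_DIVISOR) -> int:
    """Fixed-point integer for ``value``, rounding half away from zero."""
    return int(math.copysign(math.floor(abs(value) * divisor + 0.5), value))


def dequantize(value: int, divisor: int = COORD_DIVISOR) -> float:
    return value / float(divisor)


def decode_numeric_array(field: EncodedField) -> list:
    """Decode one binary field to a Python list per its strategy.

    Integer strategies yield ints, fixed-point strategies floats,
    string strategies (5, 6) strings.  Unknown ids raise
    :class:`UnsupportedCodecError`.
    """
    cid, param, payload = field.codec_id, field.parameter, field.payload
    if cid == 1:
        return np.frombuffer(payload, dtype=">f4").astype(float).tolist()
    if cid == 2:
        return _ints(payload, ">i1").tolist()
    if cid == 3:
        return _ints(payload, ">i2").tolist()
    if cid == 4:
        return _ints(payload, ">i4").tolist()
    if cid == 5:
        if param <= 0:
            raise SchemaError("string codec requires a positive width parameter")
        return [
            payload[i : i + param].rstrip(b"\x00").decode("utf-8")
            for i in range(0, len(payload), param)
        ]
    if cid == 6:
        codes = _run_length_decode(_ints(payload, ">i4"))
        return ["" if c == 0 else chr(c) for c in codes.tolist()]
    if cid == 7:
        return _run_length_decode(_ints(payload, ">i4")).tolist()
    if cid == 8:
        return np.cumsum(_run_length_decode(_ints(payload, ">i4"))).tolist()
    if cid == 9:
        return _fixed_point(_run_length_decode(_ints(payload, ">i4")), param).tolist()
    if cid == 10:
        deltas = _recursive_index_decode(_ints(payload, ">i2"), _INT16_MIN, _INT16_MAX)
        return _fixed_point(np.cumsum(np.asarray(deltas, dtype=np.int64)), param).tolist() if deltas else []
    if cid == 11:
        return _fixed_point(_ints(payload, ">i2"), param).tolist()
    if cid == 12:
        vals = _recursive_index_decode(_ints(payload, ">i2"), _INT16_MIN, _INT16_MAX)
        return _fixed_point(np.asarray(vals, dtype=np.int64), param).tolist()
    if cid == 13:
        vals = _recursive_index_decode(_ints(payload, ">i1"), _INT8_MIN, _INT8_MAX)
        return _fixed_point(np.asarray(vals, dtype=np.int64), param).tolist()
    if cid == 14:
        return _recursive_index_decode(_ints(payload, ">i2"), _INT16_MIN, _INT16_MAX)
    if cid == 15:
        return _recursive_index_decode(_ints(payload, ">i1"), _INT8_MIN, _INT8_MAX)
    raise UnsupportedCodecError(f"MMTF codec strategy {cid} is not implemented")


def encode_numeric_array(codec_id: int, values: Sequence, parameter: int = 0) -> bytes:
    """Encode a field with the given strategy, returning header + payload."""
    n = len(values)
    if codec_id == 1:
        payload = np.asarray(values, dtype=">f4").tobytes()
    elif codec_id == 2:
        payload = np.asarray(values, dtype=">i1").tobytes()
    elif codec_id == 3:
        payload = np.asarray(values, dtype=">i2").tobytes()
    elif codec_id == 4:
        payload = np.asarray(values, dtype=">i4").tobytes()
    elif codec_id == 5:
        if parameter <= 0:
            raise SchemaError("string codec requires a positive width parameter")
        chunks = []
        for s in values:
            raw = s.encode("utf-8")
            if len(raw) > parameter:
                raise SchemaError(f"string {s!r} exceeds codec width {parameter}")
            chunks.append(raw.ljust(parameter, b"\x00"))
        payload = b"".join(chunks)
    elif codec_id == 6:
        codes = [0 if s == "" else ord(s) for s in values]
        payload = np.asarray(_run_length_encode(codes), dtype=">i4").tobytes()
    elif codec_id == 7:
        payload = np.asarray(_run_length_encode(values), dtype=">i4").tobytes()
    elif codec_id == 8:
        deltas = np.diff(np.asarray(values, dtype=np.int64), prepend=0)
        payload = np.asarray(_run_length_encode(deltas.tolist()), dtype=">i4").tobytes()
    elif codec_id == 9:
        ints = [quantize(v, parameter) for v in values]
        payload = np.asarray(_run_length_encode(ints), dtype=">i4").tobytes()
    elif codec_id == 10:
        ints = np.asarray([quantize(v, parameter) for v in values], dtype=np.int64)
        if ints.size and np.abs(ints).max() > 2**31 - 1:
            raise SchemaError(
                "value exceeds the int32 fixed-point range of MMTF coordinates"
            )
        deltas = np.diff(ints, prepend=0).tolist()
        packed = _recursive_index_encode(deltas, _INT16_MIN, _INT16_MAX)
        payload = np.asarray(packed, dtype=">i2").tobytes()
    else:
        raise UnsupportedCodecError(
            f"encoding with MMTF codec strategy {codec_id} is not implemented"
        )
    return EncodedField(codec_id, parameter, payload).to_bytes(n)


# --------------------------------------------------------------------------
# whole-entry decode
# --------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "xCoordList",
    "yCoordList",
    "zCoordList",
    "groupList",
    "groupTypeList",
    "groupIdList",
    "chainIdList",
    "groupsPerChain",
    "chainsPerModel",
)


def _field(msg: dict, key: str):
    if key not in msg:
        raise SchemaError(f"required MMTF field {key!r} is missing")
    value = msg[key]
    if isinstance(value, (bytes, bytearray)):
        return decode_numeric_array(EncodedField.from_bytes(bytes(value)))
    return value


def _optional(msg: dict, key: str, default=None):
    if key not in msg:
        return default
    value = msg[key]
    if isinstance(value, (bytes, bytearray)):
        return decode_numeric_array(EncodedField.from_bytes(bytes(value)))
    return value


def _unwrap(blob: bytes, key_id: str) -> bytes:
    if blob[:2] == _GZIP_MAGIC:
        try:
            return gzip.decompress(blob)
        except (OSError, EOFError, zlib.error) as exc:
            raise DecodeError(f"record {key_id!r}: corrupt gzip stream: {exc}") from exc
    return blob


def _assembly_labels(msg: dict, n_chains: int) -> tuple[str, ...]:
    assemblies = msg.get("bioAssemblyList") or []
    labels = [""] * n_chains
    for assembly in assemblies:
        name = str(assembly.get("name", ""))
        for t_idx, transform in enumerate(assembly.get("transformList", [])):
            for chain in transform.get("chainIndexList", []):
                if 0 <= chain < n_chains and not labels[chain]:
                    labels[chain] = f"{name}.{t_idx}"
    return tuple(labels)


def decode_entry(blob: bytes, key_id: str) -> StructureEntry:
    """Decode a gzip-compressed (or raw) msgpack MMTF blob.

    Only model 1 is read; additional NMR models are skipped.  When an
    atom appears in several alternate locations, only the first-listed
    one is kept, so mining statistics never double-count; bonds that
    referenced a dropped conformer are dropped with it.
    """
    raw = _unwrap(blob, key_id)
    try:
        msg = msgpack.unpackb(raw, raw=False, strict_map_key=False)
    except Exception as exc:  # msgpack raises several unrelated types
        raise DecodeError(f"record {key_id!r}: not a msgpack MMTF blob: {exc}") from exc
    if not isinstance(msg, dict):
        raise DecodeError(f"record {key_id!r}: MMTF top level is not a map")

    for key in _REQUIRED_FIELDS:
        if key not in msg:
            raise SchemaError(f"record {key_id!r}: required MMTF field {key!r} is missing")

    xs = _field(msg, "xCoordList")
    ys = _field(msg, "yCoordList")
    zs = _field(msg, "zCoordList")
    group_types = _field(msg, "groupTypeList")
    group_ids = _field(msg, "groupIdList")
    chain_ids_all = _field(msg, "chainIdList")
    groups_per_chain = list(_field(msg, "groupsPerChain"))
    chains_per_model = list(_field(msg, "chainsPerModel"))
    group_list = msg["groupList"]
    alt_locs = _optional(msg, "altLocList")

    n_chains = int(chains_per_model[0]) if chains_per_model else 0
    n_groups = int(sum(groups_per_chain[:n_chains]))

    groups: list[Group] = []
    # global (file) atom index -> (group index, kept local atom index)
    atom_lookup: dict[int, tuple[int, int]] = {}
    atom_cursor = 0
    group_cursor = 0
    for chain_index in range(n_chains):
        for _ in range(int(groups_per_chain[chain_index])):
            g = group_cursor
            try:
                gtype = group_list[group_types[g]]
            except IndexError as exc:
                raise SchemaError(
                    f"record {key_id!r}: groupTypeList references a missing group type"
                ) from exc
            names = gtype["atomNameList"]
            elements = gtype["elementList"]
            charges = gtype.get("formalChargeList", [0] * len(names))

            kept: list[Atom] = []
            local_map: dict[int, int] = {}
            seen_names: set[str] = set()
            for local, (nm, el, ch) in enumerate(zip(names, elements, charges)):
                file_index = atom_cursor + local
                alt = alt_locs[file_index] if alt_locs is not None else ""
                if alt not in ("", "\x00") and nm in seen_names:
                    continue  # later altloc of an atom we already kept
                seen_names.add(nm)
                local_map[local] = len(kept)
                kept.append(
                    Atom(
                        name=str(nm),
                        element=str(el).upper(),
                        formal_charge=int(ch),
                        x=float(xs[file_index]),
                        y=float(ys[file_index]),
                        z=float(zs[file_index]),
                    )
                )
                atom_lookup[file_index] = (g, local_map[local])

            bonds: list[tuple[int, int, int]] = []
            bond_atoms = gtype.get("bondAtomList", [])
            bond_orders = gtype.get("bondOrderList", [1] * (len(bond_atoms) // 2))
            for b in range(len(bond_atoms) // 2):
                i, j = bond_atoms[2 * b], bond_atoms[2 * b + 1]
                if i in local_map and j in local_map and i != j:
                    ki, kj = local_map[i], local_map[j]
                    if ki > kj:
                        ki, kj = kj, ki
                    bonds.append((ki, kj, int(bond_orders[b])))

            groups.append(
                Group(
                    name=str(gtype["groupName"]).upper(),
                    comp_type=str(gtype.get("chemCompType", "")).upper(),
                    seq_id=int(group_ids[g]),
                    chain_index=chain_index,
                    atoms=tuple(kept),
                    bonds=tuple(bonds),
                )
            )
            atom_cursor += len(names)
            group_cursor += 1
            if group_cursor >= n_groups:
                break

    inter: list[tuple[tuple[int, int], tuple[int, int], int]] = []
    global_bonds = _optional(msg, "bondAtomList", [])
    global_orders = _optional(msg, "bondOrderList", [1] * (len(global_bonds) // 2))
    for b in range(len(global_bonds) // 2):
        i, j = int(global_bonds[2 * b]), int(global_bonds[2 * b + 1])
        if i in atom_lookup and j in atom_lookup:
            inter.append((atom_lookup[i], atom_lookup[j], int(global_orders[b])))

    pdb_id = (key_id or str(msg.get("structureId", ""))).upper()
    return StructureEntry(
        pdb_id=pdb_id,
        groups=tuple(groups),
        chain_ids=tuple(str(c) for c in chain_ids_all[:n_chains]),
        inter_group_bonds=tuple(inter),
        assembly_map=_assembly_labels(msg, n_chains),
    )


# --------------------------------------------------------------------------
# whole-entry encode
# --------------------------------------------------------------------------


def _parse_assembly_label(label: str) -> tuple[str, int]:
    name, _, idx = label.rpartition(".")
    if not name or not idx.isdigit():
        raise SchemaError(
            f"assembly label {label!r} is not in canonical '<name>.<index>' form"
        )
    return name, int(idx)


def _bio_assembly_list(entry: StructureEntry) -> list[dict]:
    by_assembly: dict[str, dict[int, list[int]]] = {}
    for chain_index, label in enumerate(entry.assembly_map):
        if not label:
            continue
        name, t_idx = _parse_assembly_label(label)
        by_assembly.setdefault(name, {}).setdefault(t_idx, []).append(chain_index)
    identity = [
        1.0, 0.0, 0.0, 0.0,
        0.0, 1.0, 0.0, 0.0,
        0.0, 0.0, 1.0, 0.0,
        0.0, 0.0, 0.0, 1.0,
    ]
    out = []
    for name in sorted(by_assembly):
        transforms = by_assembly[name]
        if sorted(transforms) != list(range(len(transforms))):
            raise SchemaError(
                f"assembly {name!r} transform indices are not contiguous from 0"
            )
        out.append(
            {
                "name": name,
                "transformList": [
                    {"chainIndexList": transforms[i], "matrix": identity}
                    for i in range(len(transforms))
                ],
            }
        )
    return out


def encode_entry(entry: StructureEntry) -> bytes:
    """Encode a StructureEntry as a gzip-compressed MMTF v1.0 blob.

    The inverse of :func:`decode_entry`: coordinates are stored at
    1/1000 Å fixed point, so entries whose coordinates are already
    milli-Å multiples round-trip bit-exactly.  Groups must be ordered
    by non-decreasing chain index (the MMTF traversal order).
    """
    last_chain = -1
    for group in entry.groups:
        if group.chain_index < last_chain:
            raise SchemaError(
                "groups must be ordered by non-decreasing chain index for MMTF"
            )
        last_chain = group.chain_index

    # Deduplicate group definitions into groupList entries.
    type_key_to_index: dict[tuple, int] = {}
    group_list: list[dict] = []
    group_type_list: list[int] = []
    for group in entry.groups:
        key = (
            group.name,
            group.comp_type,
            tuple(a.name for a in group.atoms),
            tuple(a.element for a in group.atoms),
            tuple(a.formal_charge for a in group.atoms),
            group.bonds,
        )
        if key not in type_key_to_index:
            type_key_to_index[key] = len(group_list)
            bond_atoms: list[int] = []
            bond_orders: list[int] = []
            for i, j, order in group.bonds:
                bond_atoms.extend((i, j))
                bond_orders.append(order)
            group_list.append(
                {
                    "groupName": group.name,
                    "atomNameList": [a.name for a in group.atoms],
                    "elementList": [a.element.capitalize() for a in group.atoms],
                    "formalChargeList": [a.formal_charge for a in group.atoms],
                    "bondAtomList": bond_atoms,
                    "bondOrderList": bond_orders,
                    "singleLetterCode": "?",
                    "chemCompType": group.comp_type,
                }
            )
        group_type_list.append(type_key_to_index[key])

    xs: list[float] = []
    ys: list[float] = []
    zs: list[float] = []
    for group in entry.groups:
        for atom in group.atoms:
            xs.append(atom.x)
            ys.append(atom.y)
            zs.append(atom.z)
    n_atoms = len(xs)
    n_groups = len(entry.groups)
    n_chains = len(entry.chain_ids)

    groups_per_chain = [0] * n_chains
    for group in entry.groups:
        groups_per_chain[group.chain_index] += 1

    atom_offsets = []  # first global atom index of each group
    cursor = 0
    for group in entry.groups:
        atom_offsets.append(cursor)
        cursor += len(group.atoms)

    global_bond_atoms: list[int] = []
    global_bond_orders: list[int] = []
    for (gi, ai), (gj, aj), order in entry.inter_group_bonds:
        global_bond_atoms.extend((atom_offsets[gi] + ai, atom_offsets[gj] + aj))
        global_bond_orders.append(order)

    chain_width = max([4] + [len(c) for c in entry.chain_ids])
    msg: dict[str, Any] = {
        "mmtfVersion": "1.0.0",
        "mmtfProducer": "structmine",
        "structureId": entry.pdb_id,
        "numModels": 1,
        "numChains": n_chains,
        "numGroups": n_groups,
        "numAtoms": n_atoms,
        "numBonds": len(global_bond_orders) + sum(len(g.bonds) for g in entry.groups),
        "chainsPerModel": [n_chains],
        "groupsPerChain": groups_per_chain,
        "chainIdList": encode_numeric_array(5, list(entry.chain_ids), chain_width),
        "chainNameList": encode_numeric_array(5, list(entry.chain_ids), chain_width),
        "groupList": group_list,
        "groupTypeList": encode_numeric_array(4, group_type_list),
        "groupIdList": encode_numeric_array(8, [g.seq_id for g in entry.groups]),
        "xCoordList": encode_numeric_array(10, xs, COORD_DIVISOR),
        "yCoordList": encode_numeric_array(10, ys, COORD_DIVISOR),
        "zCoordList": encode_numeric_array(10, zs, COORD_DIVISOR),
        "bFactorList": encode_numeric_array(10, [0.0] * n_atoms, BFACTOR_DIVISOR),
        "occupancyList": encode_numeric_array(9, [1.0] * n_atoms, 100),
        "altLocList": encode_numeric_array(6, [""] * n_atoms),
        "insCodeList": encode_numeric_array(6, [""] * n_groups),
        "secStructList": encode_numeric_array(2, [-1] * n_groups),
        "atomIdList": encode_numeric_array(8, list(range(1, n_atoms + 1))),
        "sequenceIndexList": encode_numeric_array(8, [-1] * n_groups),
        "bondAtomList": encode_numeric_array(4, global_bond_atoms),
        "bondOrderList": encode_numeric_array(2, global_bond_orders),
    }
    if any(entry.assembly_map):
        msg["bioAssemblyList"] = _bio_assembly_list(entry)

    packed = msgpack.packb(msg, use_bin_type=True)
    return gzip.compress(packed, mtime=0)
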