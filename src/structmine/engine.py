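"""Parallel map-combine executor over a sharded structure corpus.

The user supplies a *worker*: a map function ``(entry, pdb_id) ->
WorkflowResult`` plus an associative, commutative combine rule and its
identity.  The engine evaluates the map function for every corpus
entry and folds the results, under one of two scheduling models:

* ``sync`` — the shard list is split into contiguous, near-equal
  partitions, one long-lived thread per partition (578 shards on two
  workers → 289 + 289);
* ``async`` — one task per shard feeds a bounded pool, the next queued
  shard starting whenever a worker frees up.

Whatever the mode or worker count, per-shard results are combined in
manifest order, so the final result is identical across all scheduling
configurations — floating-point accumulation order included.  Threads
(not processes) carry the parallelism: each worker decodes its own
shard stream, so no decoded structure is ever shipped between workers,
and per-entry map functions are expected to be pure.

Worker failures are handled per ``RunConfig.on_error``: ``skip`` logs
the PDB ID and continues (default — one corrupt record should not kill
a full-corpus run); ``abort`` re-raises naming the entry.
"""

from __future__ import annotations

import logging
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .hadoop_io import SequenceFileError, ShardManifest, read_sequence_file
from .mmtf_codec import decode_entry
from .model import StructmineError, StructureEntry

__all__ = [
    "MergeShapeError",
    "WorkerError",
    "CountMap",
    "RowTable",
    "ScalarAccumulator",
    "combine_results",
    "WorkerSpec",
    "RunConfig",
    "RunLog",
    "RunOutcome",
    "schedule_sync",
    "schedule_async",
    "run_workflow",
    "BUILTIN_WORKFLOWS",
    "make_worker",
]

logger = logging.getLogger("structmine.engine")


class MergeShapeError(StructmineError):
    """Two results of different shapes were combined."""


class WorkerError(StructmineError):
    """A worker function failed on an entry (abort mode)."""


# --------------------------------------------------------------------------
# result shapes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMap:
    """Counts keyed by text (component IDs, histogram bins, ...)."""

    counts: dict = field(default_factory=dict)

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in sorted(self.counts.items()))


@dataclass(frozen=True)
class RowTable:
    """A table of text tuples, kept canonically sorted so outputs are
    byte-comparable across runs."""

    rows: tuple = ()

    def to_text(self) -> str:
        return "\n".join("\t".join(row) for row in self.rows)


@dataclass(frozen=True)
class ScalarAccumulator:
    """A running sum with a sample count (for means across entries)."""

    total: float = 0.0
    n: int = 0

    @property
    def mean(self) -> float:
        return self.total / self.n if self.n else 0.0

    def to_text(self) -> str:
        return f"total\t{self.total!r}\nn\t{self.n}"


WorkflowResult = CountMap | RowTable | ScalarAccumulator


def combine_results(a: WorkflowResult, b: WorkflowResult) -> WorkflowResult:
    """Associative, commutative merge of two same-shape results.

    Count maps add key-wise; row tables concatenate then sort
    lexicographically; scalar accumulators add components.
    """
    if type(a) is not type(b):
        raise MergeShapeError(
            f"cannot merge {type(a).__name__} with {type(b).__name__}"
        )
    if isinstance(a, CountMap):
        merged = dict(a.counts)
        for k, v in b.counts.items():
            merged[k] = merged.get(k, 0) + v
        return CountMap(merged)
    if isinstance(a, RowTable):
        return RowTable(tuple(sorted(a.rows + b.rows)))
    return ScalarAccumulator(a.total + b.total, a.n + b.n)


# --------------------------------------------------------------------------
# worker and run configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkerSpec:
    """A per-entry map function plus its combine rule and identity.

    ``combine(identity, r)`` must equal ``r`` for every result the map
    function can produce.  Map functions must be pure per entry: each
    invocation gets its own freshly decoded entry and shares nothing.
    """

    map_fn: Callable[[StructureEntry, str], WorkflowResult]
    identity: WorkflowResult
    combine: Callable[[WorkflowResult, WorkflowResult], WorkflowResult] = combine_results


@dataclass(frozen=True)
class RunConfig:
    n_workers: int = 1
    mode: str = "sync"
    id_filter: Optional[frozenset] = None
    on_error: str = "skip"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.mode not in ("sync", "async"):
            raise ValueError(f"mode must be 'sync' or 'async', got {self.mode!r}")
        if self.on_error not in ("abort", "skip"):
            raise ValueError(f"on_error must be 'abort' or 'skip', got {self.on_error!r}")


@dataclass
class RunLog:
    """What happened during a run: entry IDs processed, entries skipped
    with the reason, and shards that failed to read."""

    processed: list = field(default_factory=list)
    skipped: list = field(default_factory=list)  # (pdb_id, reason)
    shard_errors: list = field(default_factory=list)  # (path, reason)

    def to_text(self) -> str:
        lines = [f"processed\t{pdb_id}" for pdb_id in self.processed]
        lines += [f"skipped\t{pdb_id}\t{reason}" for pdb_id, reason in self.skipped]
        lines += [f"shard-error\t{path}\t{reason}" for path, reason in self.shard_errors]
        return "\n".join(lines)


@dataclass(frozen=True)
class RunOutcome:
    result: WorkflowResult
    log: RunLog


# --------------------------------------------------------------------------
# scheduling
# --------------------------------------------------------------------------


def schedule_sync(shards: Sequence, n_workers: int) -> list[list]:
    """Contiguous near-equal partition of the shard list.

    Every shard is assigned exactly once and partition sizes differ by
    at most one; the first ``len(shards) % n_workers`` partitions get
    the extra shard.  578 shards on two workers → 289 + 289.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    shards = list(shards)
    base, extra = divmod(len(shards), n_workers)
    partitions = []
    start = 0
    for w in range(n_workers):
        size = base + (1 if w < extra else 0)
        partitions.append(shards[start : start + size])
        start += size
    return partitions


def schedule_async(
    shards: Sequence,
    n_workers: int,
    execute: Callable,
    on_start: Optional[Callable[[int], None]] = None,
    on_finish: Optional[Callable[[int], None]] = None,
) -> list:
    """Run ``execute(shard)`` for every shard on a dynamic bounded pool.

    One task per shard; at most ``n_workers`` tasks in flight — the
    next queued shard starts when a worker completes.  Results are
    returned in shard order regardless of completion order.  The
    optional hooks receive the current in-flight count as tasks start
    and finish (used to verify the bound).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    in_flight = 0
    lock = threading.Lock()

    def task(shard):
        nonlocal in_flight
        with lock:
            in_flight += 1
            if on_start is not None:
                on_start(in_flight)
        try:
            return execute(shard)
        finally:
            with lock:
                if on_finish is not None:
                    on_finish(in_flight)
                in_flight -= 1

    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        futures = [pool.submit(task, shard) for shard in shards]
        return [f.result() for f in futures]


# --------------------------------------------------------------------------
# the run loop
# --------------------------------------------------------------------------


def _process_shard(
    path, worker: WorkerSpec, cfg: RunConfig
) -> tuple[WorkflowResult, RunLog]:
    """Decode and map every matching entry of one shard, folding
    results in record order."""
    wanted = (
        None if cfg.id_filter is None else {i.upper() for i in cfg.id_filter}
    )
    local = worker.identity
    log = RunLog()
    try:
        for record in read_sequence_file(path):
            pdb_id = record.key_text.upper()
            if wanted is not None and pdb_id not in wanted:
                continue
            try:
                entry = decode_entry(record.value, pdb_id)
                result = worker.map_fn(entry, pdb_id)
            except Exception as exc:
                if cfg.on_error == "abort":
                    raise WorkerError(f"worker failed on entry {pdb_id}: {exc}") from exc
                log.skipped.append((pdb_id, str(exc)))
                continue
            local = worker.combine(local, result)
            log.processed.append(pdb_id)
    except SequenceFileError as exc:
        if cfg.on_error == "abort":
            raise
        logger.warning("skipping rest of shard %s: %s", path, exc)
        log.shard_errors.append((str(path), str(exc)))
    return local, log


def run_workflow(
    manifest: ShardManifest, worker: WorkerSpec, cfg: RunConfig = RunConfig()
) -> RunOutcome:
    """Evaluate a worker over every corpus entry and fold the results.

    The returned result equals the sequential fold of ``combine`` over
    all entries passing the ID filter, independent of ``cfg.mode`` and
    ``cfg.n_workers``: per-shard results are always combined in
    manifest order.  The run log lists processed and skipped entries.
    """
    n_shards = len(manifest.paths)
    slots: list = [None] * n_shards

    def execute(shard_index: int) -> None:
        slots[shard_index] = _process_shard(manifest.paths[shard_index], worker, cfg)

    if cfg.mode == "sync":
        partitions = schedule_sync(range(n_shards), cfg.n_workers)
        errors: list = [None] * len(partitions)

        def run_partition(worker_index: int) -> None:
            try:
                for shard_index in partitions[worker_index]:
                    execute(shard_index)
            except BaseException as exc:  # propagate after join
                errors[worker_index] = exc

        threads = [
            threading.Thread(target=run_partition, args=(w,), name=f"structmine-sync-{w}")
            for w in range(len(partitions))
        ]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        for exc in errors:
            if exc is not None:
                raise exc
    else:
        schedule_async(range(n_shards), cfg.n_workers, execute)

    result = worker.identity
    log = RunLog()
    for slot in slots:
        shard_result, shard_log = slot
        result = worker.combine(result, shard_result)
        log.processed.extend(shard_log.processed)
        log.skipped.extend(shard_log.skipped)
        log.shard_errors.extend(shard_log.shard_errors)
    return RunOutcome(result=result, log=log)


# --------------------------------------------------------------------------
# built-in workflows
# --------------------------------------------------------------------------


def _count_ligands_worker(selector_cfg=None, blocklist=None, **_unused) -> WorkerSpec:
    """Count ligand component IDs across the corpus (simple workflow)."""
    from .calc import count_group_names
    from .prune import DEFAULT_COMMON_GROUPS, prune_common_groups
    from .select import SelectorConfig, select_small_molecules

    cfg = selector_cfg or SelectorConfig()
    block = DEFAULT_COMMON_GROUPS if blocklist is None else blocklist

    def map_fn(entry: StructureEntry, pdb_id: str) -> CountMap:
        sel = select_small_molecules(entry, cfg)
        sel = prune_common_groups(entry, sel, block)
        return CountMap(count_group_names(entry, sel))

    return WorkerSpec(map_fn=map_fn, identity=CountMap())


def _ligand_protein_contacts_worker(
    selector_cfg=None, blocklist=None, cutoff: float = 6.0, **_unused
) -> WorkerSpec:
    """List ligands with a heavy atom within ``cutoff`` Å of a protein
    residue (distance-based workflow)."""
    from .prune import DEFAULT_COMMON_GROUPS, keep_interactions, prune_common_groups
    from .select import SelectorConfig, select_peptides, select_small_molecules

    cfg = selector_cfg or SelectorConfig()
    block = DEFAULT_COMMON_GROUPS if blocklist is None else blocklist

    def map_fn(entry: StructureEntry, pdb_id: str) -> RowTable:
        ligands = prune_common_groups(
            entry, select_small_molecules(entry, cfg), block
        )
        protein = select_peptides(entry, cfg)
        kept = keep_interactions(entry, ligands, protein, cutoff, mode="keep")
        rows = tuple(
            sorted(
                (
                    pdb_id,
                    entry.groups[gi].name,
                    entry.chain_ids[entry.groups[gi].chain_index],
                    str(entry.groups[gi].seq_id),
                )
                for gi in kept.indices
            )
        )
        return RowTable(rows)

    return WorkerSpec(map_fn=map_fn, identity=RowTable())


def _bond_geometry_worker(selector_cfg=None, blocklist=None, **_unused) -> WorkerSpec:
    """Histogram ligand bond lengths and angles (complex workflow).

    The histograms ride in a CountMap keyed ``kind|elements|bin``, so
    they merge by ordinary key-wise addition.
    """
    from .calc import bond_geometry
    from .prune import DEFAULT_COMMON_GROUPS, prune_common_groups
    from .select import SelectorConfig, select_small_molecules

    cfg = selector_cfg or SelectorConfig()
    block = DEFAULT_COMMON_GROUPS if blocklist is None else blocklist

    def map_fn(entry: StructureEntry, pdb_id: str) -> CountMap:
        sel = prune_common_groups(entry, select_small_molecules(entry, cfg), block)
        stats = bond_geometry(entry, sel)
        counts = {
            f"{kind}|{elements}|{edge}": int(count)
            for kind, elements, edge, count in stats.to_rows()
        }
        return CountMap(counts)

    return WorkerSpec(map_fn=map_fn, identity=CountMap())


def _align_to_ref_worker(
    selector_cfg=None, ref_trace=None, **_unused
) -> WorkerSpec:
    """Superpose each entry's Cα trace onto a reference (complex
    workflow); emits one (pdb_id, n_points, rmsd) row per entry.

    Traces are truncated to the common length before superposition —
    correspondence is positional, no sequence alignment is attempted.
    """
    from .calc import DegeneracyError, alpha_carbon_trace, kabsch_superpose
    from .select import SelectorConfig, select_peptides

    if ref_trace is None:
        raise StructmineError("align-to-ref requires a reference trace")
    cfg = selector_cfg or SelectorConfig()

    def map_fn(entry: StructureEntry, pdb_id: str) -> RowTable:
        trace = alpha_carbon_trace(entry, select_peptides(entry, cfg))
        n = min(len(ref_trace), len(trace))
        if n < 3:
            raise DegeneracyError(f"{pdb_id}: fewer than 3 common CA positions")
        sup = kabsch_superpose(ref_trace[:n], trace[:n])
        return RowTable(((pdb_id, str(sup.n_points), f"{sup.rmsd:.4f}"),))

    return WorkerSpec(map_fn=map_fn, identity=RowTable())


def reference_trace_from_corpus(manifest: ShardManifest, selector_cfg=None):
    """Cα trace of the first decodable entry, for align-to-ref runs."""
    from .calc import alpha_carbon_trace
    from .hadoop_io import scan_corpus
    from .select import SelectorConfig, select_peptides

    cfg = selector_cfg or SelectorConfig()
    for pdb_id, blob in scan_corpus(manifest, on_error="skip"):
        try:
            entry = decode_entry(blob, pdb_id)
            return alpha_carbon_trace(entry, select_peptides(entry, cfg))
        except StructmineError:
            continue
    raise StructmineError("no corpus entry yields a usable reference trace")


#: Built-in workflow factories by CLI name.  Each factory accepts the
#: keyword arguments it understands (selector_cfg, blocklist, cutoff,
#: ref_trace) and ignores the rest.
BUILTIN_WORKFLOWS: dict[str, Callable[..., WorkerSpec]] = {
    "count-ligands": _count_ligands_worker,
    "ligand-protein-contacts": _ligand_protein_contacts_worker,
    "bond-geometry": _bond_geometry_worker,
    "align-to-ref": _align_to_ref_worker,
}


def make_worker(name: str, **kwargs) -> WorkerSpec:
    """Instantiate a built-in workflow by name."""
    try:
        factory = BUILTIN_WORKFLOWS[name]
    except KeyError:
        raise StructmineError(
            f"unknown workflow {name!r}; available: {sorted(BUILTIN_WORKFLOWS)}"
        ) from None
    return factory(**kwargs)
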