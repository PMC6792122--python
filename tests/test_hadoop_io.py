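"""Hadoop sequence-file container: round trips, dialect errors and
corpus scanning, checked against a naive spec-following parser."""

import struct

import pytest
from hypothesis import given
from hypothesis import strategies as st

from structmine.hadoop_io import (
    NotASequenceFileError,
    SequenceFileError,
    SequenceRecord,
    ShardManifest,
    TruncatedRecordError,
    UnsupportedDialectError,
    read_sequence_file,
    scan_corpus,
    write_sequence_file,
)


def naive_parse(path):
    """Independent, slice-based parser of the uncompressed Text /
    BytesWritable dialect, written directly from the container layout:
    header magic+version, two vint-prefixed class names, two flag
    bytes, int32 metadata count, 16-byte sync; then length-framed
    records with -1 sync escapes."""
    data = path.read_bytes()
    assert data[:4] == b"SEQ\x06"
    pos = 4

    def read_vint():
        nonlocal pos
        b = data[pos] - 256 if data[pos] >= 128 else data[pos]
        pos += 1
        if b >= -112:
            return b
        negative = b < -120
        n = -(b + 120) if negative else -(b + 112)
        value = int.from_bytes(data[pos : pos + n], "big")
        pos += n
        return ~value if negative else value

    for _ in range(2):  # class names
        name_len = read_vint()
        pos += name_len
    pos += 2  # compression flags
    (n_meta,) = struct.unpack(">i", data[pos : pos + 4])
    pos += 4
    assert n_meta == 0
    sync = data[pos : pos + 16]
    pos += 16
    records = []
    while pos < len(data):
        (rec_len,) = struct.unpack(">I", data[pos : pos + 4])
        pos += 4
        if rec_len == 0xFFFFFFFF:
            assert data[pos : pos + 16] == sync
            pos += 16
            continue
        (key_len,) = struct.unpack(">i", data[pos : pos + 4])
        pos += 4
        key_end = pos + key_len
        saved = pos
        text_len = read_vint()
        key = data[pos:key_end]
        assert len(key) == text_len
        pos = saved + key_len
        (blob_len,) = struct.unpack(">i", data[pos : pos + 4])
        value = data[pos + 4 : pos + 4 + blob_len]
        pos += rec_len - key_len
        records.append((key, value))
    return records


def records_of(pairs):
    return [SequenceRecord(key=k, value=v) for k, v in pairs]


class TestRoundTrip:
    def test_three_records_byte_identical(self, tmp_path):
        path = tmp_path / "shard.hadoop"
        pairs = [(b"1ABC", b"\x00\x01\x02"), (b"2XYZ", b""), (b"3DEF", b"\xff" * 10)]
        assert write_sequence_file(path, records_of(pairs)) == 3
        back = [(r.key, r.value) for r in read_sequence_file(path)]
        assert back == pairs

    def test_empty_file_round_trips(self, tmp_path):
        path = tmp_path / "empty.hadoop"
        assert write_sequence_file(path, []) == 0
        assert list(read_sequence_file(path)) == []

    def test_sync_markers_do_not_change_records(self, tmp_path):
        pairs = [(f"T{i:03d}".encode(), bytes([i]) * 50) for i in range(10)]
        dense = tmp_path / "dense.hadoop"
        sparse = tmp_path / "sparse.hadoop"
        # interval 1 forces a sync marker before every record after the first
        write_sequence_file(dense, records_of(pairs), sync_interval=1)
        write_sequence_file(sparse, records_of(pairs), sync_interval=10**6)
        assert dense.read_bytes() != sparse.read_bytes()
        read = lambda p: [(r.key, r.value) for r in read_sequence_file(p)]
        assert read(dense) == read(sparse) == pairs

    def test_agrees_with_naive_parser(self, tmp_path):
        pairs = [(f"K{i}".encode(), bytes(range(i % 256)) * 3) for i in range(25)]
        path = tmp_path / "x.hadoop"
        write_sequence_file(path, records_of(pairs), sync_interval=100)
        assert naive_parse(path) == [
            (r.key, r.value) for r in read_sequence_file(path)
        ]

    def test_order_preserved_for_many_records(self, tmp_path):
        import random

        rnd = random.Random(7)
        pairs = [
            (f"R{i:04d}".encode(), rnd.randbytes(rnd.randrange(0, 200)))
            for i in range(1000)
        ]
        path = tmp_path / "big.hadoop"
        assert write_sequence_file(path, records_of(pairs)) == 1000
        assert [r.key for r in read_sequence_file(path)] == [k for k, _ in pairs]


@given(
    st.lists(
        st.tuples(
            st.text(min_size=1, max_size=8).map(lambda s: s.encode("utf-8")),
            st.binary(max_size=300),
        ),
        max_size=20,
    )
)
def test_write_read_byte_exact_on_arbitrary_payloads(tmp_path_factory, pairs):
    path = tmp_path_factory.mktemp("seq") / "prop.hadoop"
    write_sequence_file(path, records_of(pairs), sync_interval=64)
    assert [(r.key, r.value) for r in read_sequence_file(path)] == pairs


class TestBoundedMemory:
    def test_reader_streams_one_record_at_a_time(self, tmp_path, monkeypatch):
        """Payload-size accounting: no single read request may exceed
        one record's payload, and the file is never slurped whole."""
        import structmine.hadoop_io as hio

        payload = 10_000
        pairs = [(f"B{i:03d}".encode(), bytes([i]) * payload) for i in range(30)]
        path = tmp_path / "big.hadoop"
        write_sequence_file(path, records_of(pairs))

        max_read = 0
        real_open = open

        class Accounting:
            def __init__(self, f):
                self._f = f

            def read(self, n=-1):
                nonlocal max_read
                assert n >= 0, "reader must never request the whole file"
                max_read = max(max_read, n)
                return self._f.read(n)

            def tell(self):
                return self._f.tell()

            def __enter__(self):
                return self

            def __exit__(self, *exc):
                return self._f.__exit__(*exc)

        monkeypatch.setattr(
            hio, "open", lambda p, mode="rb": Accounting(real_open(p, mode)),
            raising=False,
        )
        got = [(r.key, r.value) for r in hio.read_sequence_file(path)]
        assert got == pairs
        assert max_read <= payload + 64


class TestDialectErrors:
    def test_bad_magic(self, tmp_path):
        path = tmp_path / "bad"
        path.write_bytes(b"NOPE" + b"\x00" * 50)
        with pytest.raises(NotASequenceFileError):
            list(read_sequence_file(path))

    def test_unsupported_version(self, tmp_path):
        path = tmp_path / "v4"
        path.write_bytes(b"SEQ\x04" + b"\x00" * 50)
        with pytest.raises(UnsupportedDialectError):
            list(read_sequence_file(path))

    def test_compressed_dialect_rejected(self, tmp_path):
        good = tmp_path / "good.hadoop"
        write_sequence_file(good, records_of([(b"AAAA", b"x")]))
        data = bytearray(good.read_bytes())
        # compression flags sit right after the two class-name strings
        flag_offset = data.index(b"\x00\x00", 4)
        data[flag_offset] = 1
        bad = tmp_path / "compressed.hadoop"
        bad.write_bytes(bytes(data))
        with pytest.raises(UnsupportedDialectError, match="compress"):
            list(read_sequence_file(bad))

    def test_truncated_record_reports_offset(self, tmp_path):
        good = tmp_path / "good.hadoop"
        write_sequence_file(good, records_of([(b"AAAA", b"payload-bytes")]))
        data = good.read_bytes()
        bad = tmp_path / "trunc.hadoop"
        bad.write_bytes(data[:-5])
        with pytest.raises(TruncatedRecordError, match="byte offset"):
            list(read_sequence_file(bad))

    def test_record_key_nonempty_on_write(self, tmp_path):
        with pytest.raises(ValueError):
            write_sequence_file(
                tmp_path / "x", records_of([(b"", b"payload")])
            )


class TestScanCorpus:
    @pytest.fixture()
    def corpus(self, tmp_path):
        paths = []
        for s in range(3):
            path = tmp_path / f"shard_{s}.hadoop"
            write_sequence_file(
                path,
                records_of(
                    [(f"S{s}E{i}".encode(), bytes([s, i])) for i in range(4)]
                ),
            )
            paths.append(path)
        return ShardManifest(paths)

    def test_filter_keeps_only_requested_ids(self, corpus):
        got = list(scan_corpus(corpus, id_filter={"s0e1", "S2E3"}))
        assert [pdb_id for pdb_id, _ in got] == ["S0E1", "S2E3"]

    def test_empty_filter_yields_nothing(self, corpus):
        assert list(scan_corpus(corpus, id_filter=set())) == []

    def test_no_filter_yields_all_in_shard_order(self, corpus):
        got = [pdb_id for pdb_id, _ in scan_corpus(corpus)]
        assert got == [f"S{s}E{i}" for s in range(3) for i in range(4)]
        assert sum(corpus.record_counts.values()) == 12

    def test_corrupt_shard_skip_vs_abort(self, tmp_path):
        good = tmp_path / "a.hadoop"
        write_sequence_file(good, records_of([(b"GOOD", b"1")]))
        bad = tmp_path / "b.hadoop"
        bad.write_bytes(b"garbage that is not a sequence file")
        good2 = tmp_path / "c.hadoop"
        write_sequence_file(good2, records_of([(b"ALSO", b"2")]))
        manifest = ShardManifest([good, bad, good2])
        with pytest.raises(SequenceFileError):
            list(scan_corpus(manifest, on_error="abort"))
        got = [pdb_id for pdb_id, _ in scan_corpus(manifest, on_error="skip")]
        assert got == ["GOOD", "ALSO"]


class TestManifest:
    def test_rejects_duplicates_and_empty(self, tmp_path):
        p = tmp_path / "a"
        p.touch()
        with pytest.raises(ValueError):
            ShardManifest([p, p])
        with pytest.raises(ValueError):
            ShardManifest([])

    def test_from_dir_globs_in_sorted_order(self, tmp_path):
        for name in ("full_2.hadoop", "full_0.hadoop", "full_1.hadoop"):
            write_sequence_file(tmp_path / name, [])
        manifest = ShardManifest.from_dir(tmp_path)
        assert [p.name for p in manifest.paths] == [
            "full_0.hadoop", "full_1.hadoop", "full_2.hadoop",
        ]
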