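"""Sorted, prefix-binned, block-compressed target database.

Every PAM-matching site in the reference is encoded to a 64-bit target
word and routed to the bin named by the first ``p`` bases of its
protospacer.  Within a bin, entries are sorted by sequence bits, exact
duplicates are collapsed to one word whose 16-bit count field tallies the
genomic occurrences, and each word is followed by the packed genome
positions.  Each bin is deflate-compressed independently and the header
carries a (offset, size, checksum) index per non-empty prefix, so a search
can seek to and decompress exactly the bins it needs.  Bins whose entry
count exceeds a threshold additionally carry a nested offset table keyed
on the next four protospacer bases.

On-disk layout (little-endian)::

    magic "CRDB" | u8 format version | u64 header offset
    <compressed bin blocks, ascending prefix>
    u32 header length | header JSON

Bin payload before compression (columnar, so the reader gets numpy arrays
without a per-entry loop)::

    u32 n_entries | u32 n_positions
    n_entries  x u64   target words (count field populated, saturating)
    n_entries  x u32   positions per entry (exact, may exceed 65535)
    n_positionsx u64   packed positions, grouped by entry
    u8 has_subindex [ u32 m | u32 n_keys | n_keys x (u32 key, u32 start, u32 count) ]
"""

from __future__ import annotations

import json
import struct
import tempfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bitcodec
from .bitcodec import COUNT_MAX
from .discovery import DiscoveryStats, discover_targets, iter_fasta
from .enzymes import EnzymeSpec

MAGIC = b"CRDB"
FORMAT_VERSION = 1
DEFAULT_PREFIX_LEN = 7
SUBINDEX_THRESHOLD = 50_000
SUBINDEX_BASES = 4

#: records spilled per bucket before a flush to disk during pass 1
_SPILL_FLUSH = 262_144


class DatabaseError(RuntimeError):
    pass


@dataclass
class BinRecord:
    offset: int
    csize: int
    n_targets: int
    n_positions: int
    crc32: int
    saturated: bool = False


@dataclass
class DatabaseHeader:
    version: int
    enzyme: EnzymeSpec
    prefix_len: int
    contigs: list[tuple[str, int]]  # (name, length), index order
    bins: dict[int, BinRecord]      # prefix code -> record; absent = empty
    total_sites: int = 0
    skipped_non_acgt: int = 0

    @property
    def suffix_len(self) -> int:
        return self.enzyme.protospacer_len - self.prefix_len

    @property
    def comparison_mask(self) -> int:
        return bitcodec.comparison_mask(self.suffix_len, self.enzyme.pam_len)

    def contig_index(self, name: str) -> int:
        for i, (n, _l) in enumerate(self.contigs):
            if n == name:
                return i
        raise KeyError(name)

    def to_json(self) -> dict:
        return {
            "version": self.version,
            "enzyme": self.enzyme.to_dict(),
            "prefix_len": self.prefix_len,
            "contigs": [[n, l] for n, l in self.contigs],
            "total_sites": self.total_sites,
            "skipped_non_acgt": self.skipped_non_acgt,
            "bins": {
                str(code): [r.offset, r.csize, r.n_targets, r.n_positions,
                            r.crc32, int(r.saturated)]
                for code, r in self.bins.items()
            },
        }

    @classmethod
    def from_json(cls, d: dict) -> "DatabaseHeader":
        return cls(
            version=d["version"],
            enzyme=EnzymeSpec.from_dict(d["enzyme"]),
            prefix_len=d["prefix_len"],
            contigs=[(n, l) for n, l in d["contigs"]],
            total_sites=d["total_sites"],
            skipped_non_acgt=d["skipped_non_acgt"],
            bins={
                int(code): BinRecord(v[0], v[1], v[2], v[3], v[4], bool(v[5]))
                for code, v in d["bins"].items()
            },
        )


@dataclass
class TargetBin:
    """Decoded contents of one prefix bin (possibly empty)."""

    prefix_code: int
    prefix_len: int
    words: np.ndarray       # uint64, sorted ascending, count field set
    npos: np.ndarray        # uint32 positions per entry (exact)
    positions: np.ndarray   # uint64, grouped by entry
    sub_index: dict[int, tuple[int, int]] | None = None
    _pos_starts: np.ndarray | None = None

    @property
    def prefix(self) -> str:
        return bitcodec.decode_bases(self.prefix_code, self.prefix_len)

    @property
    def n_entries(self) -> int:
        return int(self.words.size)

    @property
    def pos_starts(self) -> np.ndarray:
        if self._pos_starts is None:
            self._pos_starts = np.concatenate(
                ([0], np.cumsum(self.npos.astype(np.int64)))
            )
        return self._pos_starts

    def entry_positions(self, i: int) -> np.ndarray:
        s = self.pos_starts
        return self.positions[s[i]: s[i + 1]]

    def entries_for_subkey(self, key_code: int) -> tuple[int, int]:
        """(start, count) slice of entries whose next SUBINDEX_BASES bases
        after the prefix equal ``key_code`` (falls back to bisect when the
        bin carries no sub-index)."""
        if self.sub_index is not None:
            return self.sub_index.get(key_code, (0, 0))
        # entries sort by sequence bits; the sub-key occupies the top bits
        shift = np.uint64(64 - 2 * SUBINDEX_BASES)
        keys = (self.words >> shift).astype(np.int64)
        lo, hi = np.searchsorted(keys, [key_code, key_code + 1])
        return int(lo), int(hi - lo)


def _empty_bin(code: int, prefix_len: int) -> TargetBin:
    return TargetBin(
        prefix_code=code, prefix_len=prefix_len,
        words=np.empty(0, np.uint64), npos=np.empty(0, np.uint32),
        positions=np.empty(0, np.uint64),
    )


def _encode_bin_payload(
    words: np.ndarray, npos: np.ndarray, positions: np.ndarray,
    subindex_threshold: int,
) -> bytes:
    parts = [struct.pack("<II", words.size, positions.size)]
    parts.append(words.astype("<u8").tobytes())
    parts.append(npos.astype("<u4").tobytes())
    parts.append(positions.astype("<u8").tobytes())
    if words.size > subindex_threshold:
        shift = np.uint64(64 - 2 * SUBINDEX_BASES)
        keys = (words >> shift).astype(np.int64)
        uniq, starts, counts = np.unique(keys, return_index=True, return_counts=True)
        parts.append(struct.pack("<BII", 1, SUBINDEX_BASES, uniq.size))
        tbl = np.empty((uniq.size, 3), dtype="<u4")
        tbl[:, 0], tbl[:, 1], tbl[:, 2] = uniq, starts, counts
        parts.append(tbl.tobytes())
    else:
        parts.append(struct.pack("<B", 0))
    return b"".join(parts)


def _decode_bin_payload(code: int, prefix_len: int, payload: bytes) -> TargetBin:
    n, tot = struct.unpack_from("<II", payload, 0)
    off = 8
    words = np.frombuffer(payload, dtype="<u8", count=n, offset=off).astype(np.uint64)
    off += 8 * n
    npos = np.frombuffer(payload, dtype="<u4", count=n, offset=off).astype(np.uint32)
    off += 4 * n
    positions = np.frombuffer(payload, dtype="<u8", count=tot, offset=off).astype(np.uint64)
    off += 8 * tot
    (has_sub,) = struct.unpack_from("<B", payload, off)
    off += 1
    sub = None
    if has_sub:
        _m, nkeys = struct.unpack_from("<II", payload, off)
        off += 8
        tbl = np.frombuffer(payload, dtype="<u4", count=3 * nkeys, offset=off).reshape(-1, 3)
        sub = {int(k): (int(s), int(c)) for k, s, c in tbl}
    return TargetBin(code, prefix_len, words, npos, positions, sub)


class _SpillBuckets:
    """Pass-1 scratch: raw (prefix code, word, position) triples routed to
    256 on-disk buckets by the first four prefix bases, so pass 2 only ever
    sorts one bucket's worth of records in memory."""

    def __init__(self, tmpdir: Path, prefix_len: int):
        self.shift = 2 * (prefix_len - 4)
        self.paths = [tmpdir / f"bucket{i:03d}.bin" for i in range(256)]
        self.handles = [open(p, "wb") for p in self.paths]
        self.pending: list[list[tuple[int, int, int]]] = [[] for _ in range(256)]
        self.n_records = 0

    def add(self, prefix_code: int, word: int, pos: int) -> None:
        b = prefix_code >> self.shift
        self.pending[b].append((prefix_code, word, pos))
        self.n_records += 1
        if len(self.pending[b]) >= _SPILL_FLUSH:
            self._flush(b)

    def _flush(self, b: int) -> None:
        if self.pending[b]:
            np.asarray(self.pending[b], dtype=np.uint64).tofile(self.handles[b])
            self.pending[b] = []

    def finish(self) -> None:
        for b in range(256):
            self._flush(b)
            self.handles[b].close()

    def load(self, b: int) -> np.ndarray:
        arr = np.fromfile(self.paths[b], dtype=np.uint64)
        return arr.reshape(-1, 3)


def build_database(
    fasta,
    enzyme: EnzymeSpec,
    out,
    prefix_len: int = DEFAULT_PREFIX_LEN,
    subindex_threshold: int = SUBINDEX_THRESHOLD,
    skip_soft_masked: bool = False,
) -> DatabaseHeader:
    """Discover every target in ``fasta`` and write the binary database.

    Two passes keep memory flat: pass 1 streams sites into 256 disk
    buckets keyed by the leading prefix bases; pass 2 sorts each bucket,
    collapses duplicate sequences (occurrence counts saturate at 65535 —
    all positions are still stored), and writes compressed bins in
    ascending prefix order.
    """
    if not 4 <= prefix_len <= enzyme.protospacer_len - 1:
        raise ValueError(
            f"prefix_len must be in [4, {enzyme.protospacer_len - 1}], got {prefix_len}"
        )
    out = Path(out)
    if not isinstance(fasta, (str, Path, dict)):
        fasta = list(fasta)  # one-shot iterables must survive two passes
    stats = DiscoveryStats()
    contigs: list[tuple[str, int]] = []
    header = DatabaseHeader(
        version=FORMAT_VERSION, enzyme=enzyme, prefix_len=prefix_len,
        contigs=contigs, bins={},
    )
    suffix_len = header.suffix_len
    pam_len = enzyme.pam_len

    with tempfile.TemporaryDirectory(prefix="guidescout-build-") as tmp, \
            open(out, "wb") as fh:
        spill = _SpillBuckets(Path(tmp), prefix_len)
        contig_idx = -1
        current = None
        for name, seq in iter_fasta(fasta):
            if any(name == n for n, _ in contigs):
                raise DatabaseError(f"duplicate contig name {name!r}")
            contigs.append((name, len(seq)))
        for site in discover_targets(
            fasta, enzyme, stats=stats, skip_soft_masked=skip_soft_masked,
        ):
            if site.contig != current:
                current = site.contig
                contig_idx = header.contig_index(site.contig)
            prefix, word = bitcodec.split_prefix(
                site.site(enzyme), prefix_len, pam_len, enzyme.pam_side
            )
            spill.add(
                bitcodec.encode_bases(prefix), word,
                bitcodec.encode_position(contig_idx, site.start, site.strand),
            )
        spill.finish()

        fh.write(MAGIC)
        fh.write(struct.pack("<B", FORMAT_VERSION))
        header_ptr_at = fh.tell()
        fh.write(struct.pack("<Q", 0))  # backpatched

        for b in range(256):
            recs = spill.load(b)
            if recs.size == 0:
                continue
            order = np.lexsort((recs[:, 2], recs[:, 1], recs[:, 0]))
            recs = recs[order]
            prefixes = recs[:, 0]
            for code in np.unique(prefixes):
                sel = recs[prefixes == code]
                _write_bin(fh, header, int(code), sel, subindex_threshold)

        header.total_sites = stats.sites_emitted
        header.skipped_non_acgt = stats.skipped_non_acgt
        header_offset = fh.tell()
        blob = json.dumps(header.to_json()).encode()
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.seek(header_ptr_at)
        fh.write(struct.pack("<Q", header_offset))
    return header


def _write_bin(fh, header: DatabaseHeader, code: int, recs: np.ndarray,
               subindex_threshold: int) -> None:
    seqs = recs[:, 1]
    uniq, starts, counts = np.unique(seqs, return_index=True, return_counts=True)
    capped = np.minimum(counts, COUNT_MAX).astype(np.uint64)
    words = uniq | capped  # count field is the low 16 bits, zero until now
    npos = counts.astype(np.uint32)
    positions = recs[:, 2]
    payload = _encode_bin_payload(words, npos, positions, subindex_threshold)
    comp = zlib.compress(payload, 6)
    header.bins[code] = BinRecord(
        offset=fh.tell(), csize=len(comp),
        n_targets=int(uniq.size), n_positions=int(positions.size),
        crc32=zlib.crc32(payload), saturated=bool((counts > COUNT_MAX).any()),
    )
    fh.write(comp)


class TargetDatabase:
    """Read-side handle: header plus seekable access to individual bins."""

    def __init__(self, path, validate: bool = False):
        self.path = Path(path)
        self.validate = validate
        self._fh = open(self.path, "rb")
        magic = self._fh.read(4)
        if magic != MAGIC:
            raise DatabaseError(f"{self.path}: not a guidescout database")
        (version,) = struct.unpack("<B", self._fh.read(1))
        if version != FORMAT_VERSION:
            raise DatabaseError(f"{self.path}: unsupported format version {version}")
        (header_offset,) = struct.unpack("<Q", self._fh.read(8))
        self._fh.seek(header_offset)
        (hlen,) = struct.unpack("<I", self._fh.read(4))
        self.header = DatabaseHeader.from_json(json.loads(self._fh.read(hlen)))

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def close(self):
        self._fh.close()

    @property
    def nonempty_prefixes(self) -> list[int]:
        return sorted(self.header.bins)

    def read_bin(self, prefix) -> TargetBin:
        """Decompress one bin; ``prefix`` is a p-base string or its code.
        An absent prefix yields an empty bin, a corrupted block a hard
        error naming the bin."""
        p = self.header.prefix_len
        if isinstance(prefix, str):
            if len(prefix) != p:
                raise ValueError(
                    f"prefix {prefix!r} is not {p} bases"
                )
            code = bitcodec.encode_bases(prefix)
        else:
            code = int(prefix)
        rec = self.header.bins.get(code)
        if rec is None:
            return _empty_bin(code, p)
        self._fh.seek(rec.offset)
        comp = self._fh.read(rec.csize)
        try:
            payload = zlib.decompress(comp)
        except zlib.error as e:
            raise DatabaseError(
                f"bin {bitcodec.decode_bases(code, p)!r}: corrupted block ({e})"
            ) from None
        if zlib.crc32(payload) != rec.crc32:
            raise DatabaseError(
                f"bin {bitcodec.decode_bases(code, p)!r}: checksum mismatch"
            )
        tbin = _decode_bin_payload(code, p, payload)
        if tbin.n_entries != rec.n_targets:
            raise DatabaseError(
                f"bin {tbin.prefix!r}: entry count disagrees with index"
            )
        if self.validate and tbin.n_entries > 1:
            seq_bits = tbin.words >> np.uint64(bitcodec.COUNT_BITS)
            if not (seq_bits[1:] > seq_bits[:-1]).all():
                raise DatabaseError(f"bin {tbin.prefix!r}: entries not sorted")
        return tbin

    def iter_bins(self):
        """All non-empty bins in ascending prefix order."""
        for code in self.nonempty_prefixes:
            yield self.read_bin(code)

    def site_multiset(self) -> dict[str, list[tuple[str, int, str]]]:
        """Full decode: site string -> list of (contig, start, strand).
        Test/inspection helper; loads everything."""
        enz = self.header.enzyme
        out: dict[str, list[tuple[str, int, str]]] = {}
        for tbin in self.iter_bins():
            prefix = tbin.prefix
            for i in range(tbin.n_entries):
                site = bitcodec.join_prefix(
                    prefix, int(tbin.words[i]), self.header.suffix_len,
                    enz.pam_len, enz.pam_side,
                )
                locs = []
                for pw in tbin.entry_positions(i):
                    ci, off, strand = bitcodec.decode_position(int(pw))
                    locs.append((self.header.contigs[ci][0], off, strand))
                out[site] = locs
        return out
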