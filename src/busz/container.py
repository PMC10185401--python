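"""The BUSZ container: block-compressed BUS files with optional barcode index.

Layout (all integers little-endian; full bit-level detail in docs/FORMAT.md):

* file header — magic ``BUSZ0001``, the BUS header fields it was built from
  (version, bc_len, umi_len, text), then block_size, the NewPFD sub-block
  size, and f stored as parts per thousand;
* per block — a header (u32 record count, u32 payload byte size) followed by
  the payload: the five column streams (barcode, umi, ec, count, flags) in
  order, each byte-aligned and prefixed with its u32 byte length.  The
  padding column is not stored and is restored as zero;
* a terminator block header of zeros ends the stream;
* optional sibling index file (``.idx``) — magic ``BUSZIDX1`` then one
  (u64 first_barcode, u64 payload size) entry per data block, enabling
  lookup of a barcode's records without decompressing the whole file.
"""

from __future__ import annotations

import struct
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import BinaryIO, Iterator

import numpy as np

from . import column_codecs as cc
from .bitstream import BitReader, BitWriter
from .bus_io import (
    BUS_DTYPE,
    RECORD_SIZE,
    BusHeader,
    _as_stream,
    first_unsorted_index,
    write_bus_header,
)
from .errors import CorruptionError, FormatError, IntegrityError, NotSortedError

__all__ = [
    "BUSZ_MAGIC",
    "INDEX_MAGIC",
    "BuszParams",
    "BuszFileHeader",
    "BlockIndexEntry",
    "CompressionSummary",
    "compress_block",
    "decompress_block",
    "compress_file",
    "decompress_file",
    "lookup_barcode",
    "read_index",
    "scan_busz",
]

BUSZ_MAGIC = b"BUSZ0001"
INDEX_MAGIC = b"BUSZIDX1"

_BLOCK_HEADER = struct.Struct("<II")
_INDEX_ENTRY = struct.Struct("<QQ")


@dataclass(frozen=True)
class BuszParams:
    """Compression parameters: records per block, NewPFD sub-block size, f."""

    block_size: int = 10_000
    n_pfd: int = 512
    f: float = 0.9

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")
        # delegate n_pfd/f validation
        self.newpfd

    @property
    def newpfd(self) -> cc.NewpfdParams:
        return cc.NewpfdParams(n_pfd=self.n_pfd, f=self.f)


@dataclass
class BuszFileHeader:
    bus: BusHeader
    params: BuszParams


@dataclass(frozen=True)
class BlockIndexEntry:
    first_barcode: int
    n_bytes: int


@dataclass
class CompressionSummary:
    n_records: int = 0
    n_blocks: int = 0
    bytes_in: int = 0
    bytes_out: int = 0

    @property
    def ratio(self) -> float:
        """Compression ratio: uncompressed size over compressed size."""
        return self.bytes_in / self.bytes_out if self.bytes_out else float("nan")


# ---------------------------------------------------------------------------
# Block codec

def _encode_column(encode, *args) -> bytes:
    w = BitWriter()
    encode(*args, w)
    w.align_to_byte()
    return w.getvalue()


def compress_block(records: np.ndarray, params: BuszParams) -> bytes:
    """Compress one sorted block of records into a self-contained payload."""
    if len(records) == 0:
        raise ValueError("cannot compress an empty block")
    bad = first_unsorted_index(records)
    if bad >= 0:
        raise NotSortedError(f"block is not sorted at record {bad}", index=bad)
    ec = records["ec"]
    if ec.min() < 0:
        raise ValueError("negative EC values cannot be compressed")
    if records["count"].min() < 1:
        raise ValueError("counts must be >= 1 in a sorted/merged BUS file")
    bc = records["barcode"]
    columns = [
        _encode_column(cc.frle0_encode, cc.delta_barcodes(bc)),
        _encode_column(cc.frle0_encode, cc.delta_umis(records["umi"], bc)),
        _encode_column(cc.newpfd_encode, ec.astype(np.int64), params.newpfd),
        _encode_column(cc.frle1_encode, records["count"]),
        _encode_column(cc.frle0_encode, records["flags"]),
    ]
    parts = []
    for col in columns:
        parts.append(struct.pack("<I", len(col)))
        parts.append(col)
    return b"".join(parts)


def decompress_block(payload: bytes, n_records: int, params: BuszParams) -> np.ndarray:
    """Exact inverse of :func:`compress_block`; padding restored as zero."""
    cols: list[bytes] = []
    pos = 0
    for _ in range(5):
        if pos + 4 > len(payload):
            raise CorruptionError("block payload ends inside a column length prefix")
        (size,) = struct.unpack_from("<I", payload, pos)
        pos += 4
        if pos + size > len(payload):
            raise CorruptionError("block payload ends inside a column stream")
        cols.append(payload[pos : pos + size])
        pos += size
    if pos != len(payload):
        raise CorruptionError(f"{len(payload) - pos} trailing bytes after the flags column")
    try:
        barcodes = cc.undelta_barcodes(
            np.array(cc.frle0_decode(BitReader(cols[0]), n_records), dtype=np.uint64)
        )
        umis = cc.undelta_umis(
            np.array(cc.frle0_decode(BitReader(cols[1]), n_records), dtype=np.uint64),
            barcodes,
        )
        ecs = cc.newpfd_decode(BitReader(cols[2]), n_records, params.newpfd)
        counts = cc.frle1_decode(BitReader(cols[3]), n_records)
        flags = cc.frle0_decode(BitReader(cols[4]), n_records)
    except (ValueError, OverflowError) as exc:
        raise CorruptionError(f"undecodable column stream: {exc}") from exc
    out = np.empty(n_records, dtype=BUS_DTYPE)
    out["barcode"] = barcodes
    out["umi"] = umis
    out["ec"] = ecs
    out["count"] = counts
    out["flags"] = flags
    out["pad"] = 0
    return out


# ---------------------------------------------------------------------------
# File header I/O

def _write_busz_header(header: BuszFileHeader, stream: BinaryIO) -> int:
    bus, params = header.bus, header.params
    data = BUSZ_MAGIC + struct.pack(
        "<4I", bus.version, bus.bc_len, bus.umi_len, len(bus.text)
    ) + bus.text + struct.pack(
        "<3I", params.block_size, params.n_pfd, round(params.f * 1000)
    )
    stream.write(data)
    return len(data)


def read_busz_header(stream: BinaryIO) -> BuszFileHeader:
    magic = stream.read(8)
    if magic != BUSZ_MAGIC:
        raise FormatError(f"not a BUSZ file (magic {magic!r})")
    fixed = stream.read(16)
    if len(fixed) != 16:
        raise CorruptionError("file ends inside the BUSZ header")
    version, bc_len, umi_len, tlen = struct.unpack("<4I", fixed)
    text = stream.read(tlen)
    tail = stream.read(12)
    if len(text) != tlen or len(tail) != 12:
        raise CorruptionError("file ends inside the BUSZ header")
    block_size, n_pfd, f_ppt = struct.unpack("<3I", tail)
    return BuszFileHeader(
        bus=BusHeader(version=version, bc_len=bc_len, umi_len=umi_len, text=text),
        params=BuszParams(block_size=block_size, n_pfd=n_pfd, f=f_ppt / 1000),
    )


# ---------------------------------------------------------------------------
# Whole-file operations

def compress_file(
    bus_in,
    busz_out,
    params: BuszParams = BuszParams(),
    write_index: bool = False,
    index_out=None,
) -> CompressionSummary:
    """Compress a sorted BUS file into BUSZ; optionally emit the barcode index.

    ``bus_in``/``busz_out`` may be paths or binary streams.  The index is
    written to ``index_out`` or, for a path output, to ``<busz_out>.idx``.
    """
    from .bus_io import read_bus

    bus_header, records = read_bus(bus_in)
    bad = first_unsorted_index(records)
    if bad >= 0:
        raise NotSortedError(
            f"input is not sorted by (barcode, umi, ec) at record {bad}", index=bad
        )
    if len(records) and records["pad"].any():
        warnings.warn(
            "input has nonzero padding bytes; they are not stored and will "
            "decompress as zero",
            stacklevel=2,
        )
    summary = CompressionSummary(
        n_records=len(records),
        bytes_in=bus_header.size + RECORD_SIZE * len(records),
    )
    index: list[BlockIndexEntry] = []
    with _as_stream(busz_out, "wb") as out:
        n = _write_busz_header(BuszFileHeader(bus=bus_header, params=params), out)
        for start in range(0, len(records), params.block_size):
            block = records[start : start + params.block_size]
            payload = compress_block(block, params)
            out.write(_BLOCK_HEADER.pack(len(block), len(payload)))
            out.write(payload)
            n += _BLOCK_HEADER.size + len(payload)
            index.append(BlockIndexEntry(int(block["barcode"][0]), len(payload)))
            summary.n_blocks += 1
        out.write(_BLOCK_HEADER.pack(0, 0))  # terminator
        n += _BLOCK_HEADER.size
    summary.bytes_out = n
    if write_index:
        if index_out is None:
            if not (isinstance(busz_out, (str, bytes)) or hasattr(busz_out, "__fspath__")):
                raise ValueError("index_out is required when busz_out is a stream")
            index_out = str(busz_out) + ".idx"
        with _as_stream(index_out, "wb") as idx:
            idx.write(INDEX_MAGIC)
            for entry in index:
                idx.write(_INDEX_ENTRY.pack(entry.first_barcode, entry.n_bytes))
    return summary


def _iter_blocks(stream: BinaryIO) -> Iterator[tuple[int, int, bytes]]:
    """Yield (ordinal, n_records, payload) per data block, until the terminator."""
    ordinal = 0
    while True:
        head = stream.read(_BLOCK_HEADER.size)
        if len(head) != _BLOCK_HEADER.size:
            raise CorruptionError(f"file ends inside the header of block {ordinal}")
        n_records, n_bytes = _BLOCK_HEADER.unpack(head)
        if n_records == 0 and n_bytes == 0:
            return
        if n_records == 0:
            raise CorruptionError(f"block {ordinal} has 0 records but {n_bytes} bytes")
        payload = stream.read(n_bytes)
        if len(payload) != n_bytes:
            raise CorruptionError(f"file ends inside the payload of block {ordinal}")
        yield ordinal, n_records, payload
        ordinal += 1


def decompress_file(busz_in, bus_out) -> CompressionSummary:
    """Decompress a BUSZ file back to an identical plain BUS file."""
    summary = CompressionSummary()
    with _as_stream(busz_in, "rb") as src:
        header = read_busz_header(src)
        with _as_stream(bus_out, "wb") as out:
            n = write_bus_header(header.bus, out)
            for ordinal, n_records, payload in _iter_blocks(src):
                try:
                    block = decompress_block(payload, n_records, header.params)
                except CorruptionError as exc:
                    raise CorruptionError(f"block {ordinal}: {exc}") from exc
                out.write(block.tobytes())
                summary.n_blocks += 1
                summary.n_records += n_records
                summary.bytes_in += _BLOCK_HEADER.size + len(payload)
            summary.bytes_out = n + RECORD_SIZE * summary.n_records
    return summary


def read_index(index_in) -> list[BlockIndexEntry]:
    with _as_stream(index_in, "rb") as fh:
        magic = fh.read(8)
        if magic != INDEX_MAGIC:
            raise FormatError(f"not a BUSZ index file (magic {magic!r})")
        data = fh.read()
    if len(data) % _INDEX_ENTRY.size:
        raise CorruptionError("index file has a partial entry")
    return [
        BlockIndexEntry(*_INDEX_ENTRY.unpack_from(data, off))
        for off in range(0, len(data), _INDEX_ENTRY.size)
    ]


def lookup_barcode(busz_in, index, barcode: int) -> np.ndarray:
    """Return exactly the records with ``barcode``, decompressing only the
    blocks whose barcode range may contain it.

    ``index`` is a list of :class:`BlockIndexEntry` or a path/stream of an
    index file.  A barcode's records may straddle block boundaries, so the
    block preceding the first index hit is always examined too.
    """
    if not isinstance(index, list):
        index = read_index(index)
    firsts = [e.first_barcode for e in index]
    if firsts != sorted(firsts):
        raise IntegrityError("index first_barcode entries are not sorted")
    lo = bisect_left(firsts, barcode)
    hi = bisect_right(firsts, barcode) - 1
    lo = max(lo - 1, 0)
    if hi < lo:
        hi = lo
    # block i's header sits at base + offsets[i]
    offsets = [0]
    for e in index:
        offsets.append(offsets[-1] + _BLOCK_HEADER.size + e.n_bytes)
    with _as_stream(busz_in, "rb") as src:
        header = read_busz_header(src)
        if not index:
            return np.empty(0, dtype=BUS_DTYPE)
        base = src.tell()
        matches: list[np.ndarray] = []
        for i in range(lo, hi + 1):
            src.seek(base + offsets[i])
            head = src.read(_BLOCK_HEADER.size)
            if len(head) != _BLOCK_HEADER.size:
                raise IntegrityError(f"index points past the end of the file at block {i}")
            n_records, n_bytes = _BLOCK_HEADER.unpack(head)
            if n_bytes != index[i].n_bytes or n_records == 0:
                raise IntegrityError(
                    f"index and file disagree on block {i} "
                    f"({index[i].n_bytes} vs {n_bytes} bytes)"
                )
            payload = src.read(n_bytes)
            if len(payload) != n_bytes:
                raise IntegrityError(f"file ends inside block {i} named by the index")
            block = decompress_block(payload, n_records, header.params)
            matches.append(block[block["barcode"] == barcode])
    if not matches:
        return np.empty(0, dtype=BUS_DTYPE)
    return np.concatenate(matches)


def scan_busz(busz_in) -> tuple[BuszFileHeader, list[dict]]:
    """Per-block metadata (record count, payload size, per-column sizes)
    without decoding any column stream."""
    blocks: list[dict] = []
    with _as_stream(busz_in, "rb") as src:
        header = read_busz_header(src)
        for ordinal, n_records, payload in _iter_blocks(src):
            sizes = []
            pos = 0
            for _ in range(5):
                if pos + 4 > len(payload):
                    raise CorruptionError(f"block {ordinal}: truncated column prefix")
                (size,) = struct.unpack_from("<I", payload, pos)
                sizes.append(size)
                pos += 4 + size
            blocks.append(
                {"n_records": n_records, "n_bytes": len(payload), "column_bytes": sizes}
            )
    return header, blocks
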