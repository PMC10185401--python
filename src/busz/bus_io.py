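"""Reading, writing, sorting and merging plain BUS files.

A BUS file is a small header followed by fixed 32-byte records.  Each record
holds a cell barcode and a UMI (both 2-bit-encoded nucleotide strings stored
as unsigned 64-bit integers), an equivalence-class id (signed 32-bit), a read
count, a flags word, and 4 bytes of zero padding.  All integers are
little-endian.  Records are canonically sorted lexicographically by
(barcode, umi, ec), and records sharing that full key are merged with their
counts summed.

In memory a batch of records is a NumPy structured array with dtype
:data:`BUS_DTYPE`; :class:`BusRecord` is a per-record convenience tuple.
"""

from __future__ import annotations

import contextlib
import struct
from dataclasses import dataclass
from typing import BinaryIO, Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .errors import FormatError, TruncatedStreamError

__all__ = [
    "BUS_MAGIC",
    "BUS_DTYPE",
    "RECORD_SIZE",
    "BusHeader",
    "BusRecord",
    "encode_sequence",
    "decode_sequence",
    "read_bus",
    "write_bus",
    "sort_and_merge",
    "records_from_tuples",
    "first_unsorted_index",
]

BUS_MAGIC = b"BUS\x00"
RECORD_SIZE = 32

#: On-disk record layout: u64 barcode, u64 umi, i32 ec, u32 count, u32 flags,
#: u32 padding — 8+8+4+4+4+4 = 32 bytes, little-endian.
BUS_DTYPE = np.dtype(
    [
        ("barcode", "<u8"),
        ("umi", "<u8"),
        ("ec", "<i4"),
        ("count", "<u4"),
        ("flags", "<u4"),
        ("pad", "<u4"),
    ]
)
assert BUS_DTYPE.itemsize == RECORD_SIZE

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_NT_CHAR = "ACGT"


class BusRecord(NamedTuple):
    """One BUS record; padding is implicit (always written as zero)."""

    barcode: int
    umi: int
    ec: int
    count: int = 1
    flags: int = 0


@dataclass
class BusHeader:
    """BUS file header: format version, barcode/UMI lengths, free text."""

    version: int = 1
    bc_len: int = 16
    umi_len: int = 12
    text: bytes = b""

    def __post_init__(self) -> None:
        if not 1 <= self.bc_len <= 32:
            raise FormatError(f"bc_len must be in 1..32, got {self.bc_len}")
        if not 1 <= self.umi_len <= 32:
            raise FormatError(f"umi_len must be in 1..32, got {self.umi_len}")
        if isinstance(self.text, str):
            self.text = self.text.encode()

    @property
    def size(self) -> int:
        """Serialized header size in bytes."""
        return 4 + 4 * 4 + len(self.text)


def encode_sequence(seq: str) -> int:
    """2-bit-encode a nucleotide string (A=00, C=01, G=10, T=11) into a u64.

    The leftmost base occupies the most significant bit pair.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if len(seq) > 32:
        raise ValueError(f"sequence length {len(seq)} exceeds 32 nucleotides")
    code = 0
    for pos, ch in enumerate(seq):
        try:
            code = (code << 2) | _NT_CODE[ch]
        except KeyError:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {pos} (expected A/C/G/T)"
            ) from None
    return code


def decode_sequence(code: int, length: int) -> str:
    """Inverse of :func:`encode_sequence` for a known sequence length."""
    if not 1 <= length <= 32:
        raise ValueError(f"length must be in 1..32, got {length}")
    if not 0 <= code < 4**length:
        raise ValueError(f"code {code} out of range for {length} nucleotides")
    return "".join(_NT_CHAR[(code >> (2 * (length - 1 - i))) & 3] for i in range(length))


@contextlib.contextmanager
def _as_stream(obj, mode: str) -> Iterator[BinaryIO]:
    if isinstance(obj, (str, bytes)) or hasattr(obj, "__fspath__"):
        with open(obj, mode) as fh:
            yield fh
    else:
        yield obj


def _read_exact(stream: BinaryIO, n: int, what: str) -> bytes:
    data = stream.read(n)
    if len(data) != n:
        raise TruncatedStreamError(f"file ended while reading {what}")
    return data


def read_bus_header(stream: BinaryIO) -> BusHeader:
    magic = _read_exact(stream, 4, "BUS magic")
    if magic != BUS_MAGIC:
        raise FormatError(f"not a BUS file (magic {magic!r})")
    version, bc_len, umi_len, tlen = struct.unpack("<4I", _read_exact(stream, 16, "BUS header"))
    text = _read_exact(stream, tlen, "BUS header text")
    return BusHeader(version=version, bc_len=bc_len, umi_len=umi_len, text=text)


def write_bus_header(header: BusHeader, stream: BinaryIO) -> int:
    data = BUS_MAGIC + struct.pack(
        "<4I", header.version, header.bc_len, header.umi_len, len(header.text)
    ) + header.text
    stream.write(data)
    return len(data)


def read_bus(source) -> tuple[BusHeader, np.ndarray]:
    """Read a BUS file (path or binary stream) into (header, records array)."""
    with _as_stream(source, "rb") as stream:
        header = read_bus_header(stream)
        payload = stream.read()
    if len(payload) % RECORD_SIZE:
        raise TruncatedStreamError(
            f"record payload of {len(payload)} bytes is not a multiple of {RECORD_SIZE}"
        )
    records = np.frombuffer(payload, dtype=BUS_DTYPE).copy()
    return header, records


def write_bus(header: BusHeader, records: np.ndarray | Sequence[BusRecord], dest) -> int:
    """Write a BUS file; padding is always written as zero.  Returns bytes written."""
    arr = records_from_tuples(records) if not isinstance(records, np.ndarray) else records
    if arr.dtype != BUS_DTYPE:
        raise ValueError(f"records must have dtype {BUS_DTYPE}")
    if arr.size and arr["pad"].any():
        arr = arr.copy()
        arr["pad"] = 0
    with _as_stream(dest, "wb") as stream:
        n = write_bus_header(header, stream)
        stream.write(arr.tobytes())
    return n + RECORD_SIZE * len(arr)


def records_from_tuples(records: Iterable[tuple]) -> np.ndarray:
    """Build a :data:`BUS_DTYPE` array from an iterable of BusRecord/tuples."""
    rows = [(r[0], r[1], r[2], r[3], r[4], 0) for r in (BusRecord(*t) for t in records)]
    return np.array(rows, dtype=BUS_DTYPE)


def first_unsorted_index(records: np.ndarray, strict: bool = False) -> int:
    """Index of the first record that breaks (barcode, umi, ec) order, or -1.

    With ``strict`` the full key must strictly increase (sorted *and* merged).
    """
    if len(records) < 2:
        return -1
    bc, umi, ec = records["barcode"], records["umi"], records["ec"]
    bc_gt = bc[1:] > bc[:-1]
    bc_eq = bc[1:] == bc[:-1]
    umi_gt = umi[1:] > umi[:-1]
    umi_eq = umi[1:] == umi[:-1]
    ec_ok = ec[1:] > ec[:-1] if strict else ec[1:] >= ec[:-1]
    ok = bc_gt | (bc_eq & (umi_gt | (umi_eq & ec_ok)))
    bad = np.flatnonzero(~ok)
    return int(bad[0]) + 1 if bad.size else -1


def sort_and_merge(records: np.ndarray) -> np.ndarray:
    """Sort by (barcode, umi, ec) and merge records sharing that full key.

    Merged records get the sum of the counts and the bitwise OR of the flags;
    the total read count is conserved.  Idempotent.
    """
    if len(records) == 0:
        return records.copy()
    order = np.lexsort((records["ec"], records["umi"], records["barcode"]))
    srt = records[order]
    key_change = np.empty(len(srt), dtype=bool)
    key_change[0] = True
    key_change[1:] = (
        (srt["barcode"][1:] != srt["barcode"][:-1])
        | (srt["umi"][1:] != srt["umi"][:-1])
        | (srt["ec"][1:] != srt["ec"][:-1])
    )
    starts = np.flatnonzero(key_change)
    out = srt[starts].copy()
    counts = np.add.reduceat(srt["count"].astype(np.uint64), starts)
    if counts.max(initial=0) > np.iinfo(np.uint32).max:
        raise OverflowError("merged read count exceeds the u32 range")
    out["count"] = counts.astype(np.uint32)
    out["flags"] = np.bitwise_or.reduceat(srt["flags"], starts)
    out["pad"] = 0
    return out
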