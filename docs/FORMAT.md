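# BUSZ on-disk format (this implementation)

This document specifies the exact byte and bit layout produced by this
package.  All fixed-width integers are **little-endian**.  All bit streams
are packed **MSB-first** within each byte.  This layout is self-contained
and is the authority for this implementation; byte-level compatibility with
other BUSZ writers is not a goal.

## Plain BUS file

```
magic    4 bytes   "BUS\0"
version  u32
bc_len   u32       nucleotides per barcode (1..32)
umi_len  u32       nucleotides per UMI (1..32)
tlen     u32       length of the free text that follows
text     tlen bytes
records  n * 32 bytes
```

Each record (32 bytes): `u64 barcode, u64 umi, i32 ec, u32 count, u32 flags,
u32 padding`.  Barcodes and UMIs are 2-bit-encoded nucleotides (A=00, C=01,
G=10, T=11, leftmost base most significant).  Padding is always written as
zero.

## BUSZ file

```
magic       8 bytes  "BUSZ0001"
version     u32      copied from the input BUS header
bc_len      u32
umi_len     u32
tlen        u32      + text bytes, copied from the input BUS header
block_size  u32      records per block (default 10000)
n_pfd       u32      NewPFD sub-block size (default 512)
f_ppt       u32      in-range fraction f in parts per thousand (0.9 -> 900)
```

followed by zero or more data blocks and a terminator:

```
block header   u32 n_records (1 <= n <= block_size), u32 n_bytes (payload size)
block payload  n_bytes bytes
...
terminator     u32 0, u32 0
```

Only the final data block may hold fewer than `block_size` records.

### Block payload

Five column streams in order **barcode, umi, ec, count, flags** (the padding
column is not stored).  Each stream is independently byte-aligned (zero
padding bits at the end) and prefixed with its byte length:

```
u32 len_barcode, barcode stream, u32 len_umi, umi stream, ..., u32 len_flags, flags stream
```

### Fibonacci codewords

A positive integer `v` is written as its Zeckendorf representation over
F1=1, F2=2, F3=3, F4=5, ... — the coefficient of F1 first — terminated by
one extra 1 bit.  Every codeword ends in `11` and contains no other adjacent
1 pair.  Examples: 1 → `11`, 3 → `0011`, 4 → `1011`, 11 → `001011`.

### FRLE0 (barcode deltas, UMI deltas, flags)

The value list is run-length encoded over zeros: each maximal run of L
zeros becomes the marker/length pair, every other value is literal.

* literal `v`        → fib(v + 1)   (the +1 because Fibonacci codes cannot encode 0)
* run of L zeros     → fib(1), fib(L)   (run lengths are >= 1, no increment)

A length-1 run of zeros is still `fib(1), fib(1)`.  Decoding reads
codewords until exactly `n_records` values are produced; `fib(1)` always
introduces a run length.

### FRLE1 (counts)

Counts are strictly positive; runs of **ones** are collapsed:

* literal `v >= 2`   → fib(v)
* run of L ones      → fib(1), fib(L)

### Barcode column

`delta[0] = barcode[0]` (raw; blocks decode independently),
`delta[i] = barcode[i] − barcode[i−1]` (non-negative by sort order), then
FRLE0.

### UMI column

`delta[0] = umi[0]`; for i > 0, if `barcode[i] == barcode[i−1]` then
`delta[i] = umi[i] − umi[i−1]`, otherwise the raw `umi[i]`.  Then FRLE0.
Decoding first reconstructs the barcode column, which determines where raw
values restart.

Note: a raw u64 value of 2^64−1 becomes 2^64 after the FRLE0 increment;
the Fibonacci coder therefore supports values up to 2^64 inclusive.

### EC column (NewPFD)

The EC list of the block (values as-is, no delta) is split into sub-blocks
of `n_pfd` consecutive values; the final sub-block of a block may be short
(its actual length `|B|` is known from `n_records`).  For each sub-block:

* `k` = minimum of the sub-block;
* `b` = bit length of the `ceil(f·|B|)`-th smallest offset `(x − k)`
  (the minimal width such that at least that many offsets fit; the bit
  length of 0 is 0), capped at 32;
* an **exception** is any value whose offset needs more than `b` bits,
  i.e. `(x − k) >> b != 0`.

Sub-block stream:

```
fib(b + 1)
fib(k + 1)
fib(n_exceptions + 1)
per exception, in position order:
    fib(pos − prev + 1)      prev starts at 0, then the previous exception's pos
    fib((x − k) >> b)        high bits, >= 1 by construction (no increment)
|B| fixed b-bit slots        (x − k) & (2^b − 1), omitted entirely when b = 0
```

Decoding: `pos = prev + decoded − 1`, then `prev = pos`.

## Index file (optional, sibling `.idx`)

```
magic    8 bytes  "BUSZIDX1"
per data block:
    u64 first_barcode   (non-decreasing)
    u64 n_bytes         (compressed payload size, equal to the block header's)
```

Block byte offsets are reconstructed by cumulative sums of
`8 + n_bytes` starting immediately after the BUSZ file header.  Because one
barcode's records may straddle block boundaries, a reader looking up
barcode `q` must also examine the block preceding the first block whose
`first_barcode` equals `q` (or, when no block starts with `q`, the last
block with `first_barcode < q`).
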