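# Methods

## The problem

Sorted BUS files from single-cell RNA-seq pipelines are long runs of
fixed 32-byte records — (cell barcode, UMI, equivalence class, count,
flags, padding) — in which adjacent records are highly similar: the same
cell contributes many consecutive records, UMIs are non-decreasing within a
cell, read counts are overwhelmingly 1 and flags overwhelmingly 0.  Generic
byte-oriented compressors see none of this structure.  This package
compresses such files column by column, block by block, and decompresses
them byte-identically.

## The scheme

Input records must already be sorted lexicographically by
(barcode, UMI, EC); the compressor refuses unsorted input rather than
sorting it, because sorting (which merges duplicate keys) changes the file
and belongs to the upstream pipeline.  Records are chunked into blocks of
`block_size` (default 10 000) records, and within a block each column is
encoded independently so that blocks — and columns within a block — can be
decoded in isolation:

| column  | transform                                   | entropy coder |
|---------|---------------------------------------------|---------------|
| barcode | delta vs. previous record                   | FRLE0         |
| UMI     | delta vs. previous record of the same cell  | FRLE0         |
| EC      | none                                        | NewPFD        |
| count   | none                                        | FRLE1         |
| flags   | none                                        | FRLE0         |
| padding | not stored; restored as zero                | —             |

FRLE0/FRLE1 are run-length encodings of zeros/ones whose token streams are
written with the Fibonacci universal code (docs/FORMAT.md gives the exact
bit layout).  The Fibonacci code was chosen over Elias codes for its
robustness and density on the small values that dominate here; since it
cannot represent zero, literal values in FRLE0 are incremented by one.  Run
lengths and FRLE1 literals are already positive and are not incremented.

The EC column has much higher entropy than its neighbours, so it gets a
patched frame-of-reference codec (NewPFD): sub-blocks of `n_pfd` (default
512) values are stored as fixed `b`-bit offsets from the sub-block minimum
`k`, and the minority of values that do not fit — at most a `1 − f`
fraction, default `f` = 0.9 — are "exceptions" whose remaining high bits
are Fibonacci-coded separately.  `b` is chosen minimally as the bit length
of the `ceil(f·|B|)`-th smallest offset, so the f-fraction guarantee holds
by construction on every sub-block (the test suite audits this on the
encoded stream, not the encoder's intermediate state).  ECs are encoded
as-is rather than delta-coded: they are not monotone, and `k` already
absorbs the block-local offset.

### Numerical and layout choices

* One global bit convention (MSB-first) for both Fibonacci codewords and
  fixed-width slots; every column stream is byte-aligned and
  length-prefixed so a damaged column is localizable and skippable.
* The first barcode of each block is stored raw, and the UMI codec restarts
  with a raw value at every barcode change, so each block decodes without
  its predecessors — the property the barcode index relies on.
* The Fibonacci coder accepts values up to 2^64 *inclusive*: a u64 field at
  its maximum becomes 2^64 after the FRLE0 pre-increment.
* `b` is capped at 32 bits; EC values are signed-positive 32-bit so offsets
  always fit and the cap only bounds pathological headers.
* Negative ECs (used by some tools as sentinels) are rejected at
  compression time with a clear error — the offset arithmetic assumes
  non-negative values.
* Merging duplicate keys sums counts and bitwise-ORs flags: summation
  conserves total read count, OR never drops a set flag bit.
* End of stream is an explicit all-zero block header rather than an
  EOF-based convention.
* The stored `f` (parts per thousand) is informational: decoding only needs
  the explicit per-sub-block `k`, `b` and exception lists.

## Random access

An optional sibling index stores (first barcode, compressed size) per
block.  Lookup binary-searches the first-barcode list and decompresses only
the candidate block range; since one barcode's records can straddle a block
boundary, the block preceding the first hit is always inspected as well.
Correctness is tested exhaustively against full-decompress-then-filter on a
fixture built to straddle boundaries.

## Synthetic data

The generator emulates exactly the structural assumptions the codecs
exploit, with defaults sketching a modest droplet experiment:

* `n_cells` = 100 distinct 16 nt barcodes, sorted; ~`mean_umis_per_cell`
  = 100 Poisson-distributed molecules each with uniform 12 nt UMIs —
  producing the barcode runs and within-cell UMI ordering the delta coders
  expect;
* ECs drawn from a Zipf-like categorical over `n_ecs` = 1000 classes with
  exponent `ec_concentration` = 1.2 — a higher-entropy column, tunable from
  near-uniform to highly skewed;
* counts 1 plus a geometric excess with probability `p_count_gt1` = 0.1;
  flags set with probability `p_flag_set` = 0.01;
* output is passed through sort-and-merge, so it always satisfies the
  sorted-file invariants; fully deterministic given the seed (default
  20230502).

It does **not** model barcode whitelists, sequencing error, transcriptome
structure, or realistic EC-class sizes.  Passing the losslessness and
compression tests on this data therefore demonstrates correctness of the
codecs and the expected *direction* of the compression gain on
redundantly-structured input — not the compression ratio any particular
real dataset will achieve.  Adversarial generators cover the degenerate
shapes random data misses: a single repeated key, strictly increasing
columns (worst case for RLE), every field at its representable maximum, and
a barcode whose records straddle a block boundary.

## Scale of the shipped experiments

Tests and the acceptance script run on synthetic files of up to ~10^5
records (about 3 MB raw), a size at which every code path — multi-block
files, short final blocks and sub-blocks, exception-heavy EC sub-blocks —
is exercised while the whole suite stays fast.  The gzip comparison uses
`gzip -1` on identical raw bytes and asserts direction only (the columnar
file is smaller); measured ratios on the default synthetic profile are
around 7× versus gzip's ~4×.

## Known limitations

* The whole input is held in memory for sorting and compression; external
  sorting of very large files is out of scope.
* The on-disk layout is this package's own (documented in
  docs/FORMAT.md); it is not byte-compatible with other BUSZ writers.
* Nonzero padding bytes in the input are not preserved (a warning is
  emitted); everything else round-trips byte-identically.
* Pure-Python bit coding favours clarity over throughput; the
  implementation compresses a few hundred thousand records per second,
  which is ample for fixtures and desk-scale files but not for
  terabyte-scale archives.
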