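# busz — lossless columnar compression for sorted BUS files

Single-cell RNA-seq pipelines built around the BUS format ("Barcode, UMI,
Set") store one fixed 32-byte record per observed molecule: the cell
barcode and UMI as 2-bit-encoded nucleotide integers, an equivalence-class
(EC) id for the transcript set the read is compatible with, a read count,
and a flags word.  Sorted BUS files are what labs archive for
reproducibility, and they are highly redundant — thousands of consecutive
records share a barcode, counts are almost all 1, flags almost all 0.
Generic compressors ignore that structure.

This package compresses sorted BUS files **losslessly** with a columnar,
block-based scheme, and decompresses them byte-identically:

* records are chunked into blocks of N records (default N = 10 000); each
  of the five stored columns is compressed independently per block;
* **barcode**: deltas of adjacent barcodes (non-negative by sort order),
  then Fibonacci-coded run-length encoding of zeros (FRLE₀);
* **UMI**: deltas taken only between records of the same cell, the raw
  value at each cell change, then FRLE₀;
* **EC**: a NewPFD patched frame-of-reference codec — sub-blocks of
  N_PFD values (default 512) stored as fixed b-bit offsets from the
  sub-block minimum k, with b chosen so that at least a fraction f
  (default 0.9) of values fit and the outliers escaped as Fibonacci-coded
  exceptions;
* **count**: FRLE₁ (runs of ones collapsed); **flags**: FRLE₀; the padding
  column is dropped and restored as zero.

Block headers record sizes, so files stream; an optional index of (first
barcode, block size) per block gives random access to one barcode's records
without decompressing the rest.  The exact bit layout is specified in
[docs/FORMAT.md](docs/FORMAT.md); the design rationale in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a deterministic synthetic sorted BUS file (500 cells, ~80
molecules each), compress it with an index, inspect, and round-trip:

```console
$ busz generate --cells 500 --mean-umis 80 --seed 7 example.bus
records=40160
$ busz compress --index example.bus example.busz
records=40160 blocks=5 bytes_in=1285168 bytes_out=180934 ratio=7.103
$ busz inspect example.busz
format=BUSZ version=1 bc_len=16 umi_len=12
block_size=10000 pfd_size=512 pfd_fraction=0.9
records=40160 blocks=5
column_bytes[barcode]=2860
column_bytes[umi]=127546
column_bytes[ec]=44553
column_bytes[count]=5031
column_bytes[flags]=732
$ busz decompress example.busz back.bus && cmp example.bus back.bus && echo IDENTICAL
records=40160 blocks=5 bytes_out=1285168
IDENTICAL
```

The 1.23 MB input compresses 7.1× to 177 KB.  The per-column sizes show
why the scheme works: 40 160 barcodes cost only 2 860 bytes (long runs of
zero deltas), counts and flags almost vanish, and the high-entropy UMI and
EC columns dominate the output.  With the index present, one cell's
records come back without a full decompression:

```console
$ busz lookup --barcode CTTTGTGAGAGCACAC example.busz | head -3
CTTTGTGAGAGCACAC	AAACTGTGAGTG	118	1	0
CTTTGTGAGAGCACAC	AACCCGTGCTTT	79	1	0
CTTTGTGAGAGCACAC	AAGCATTAGGTG	77	1	0
```

The same operations are available as a library: `busz.compress_file`,
`busz.decompress_file`, `busz.lookup_barcode`, `busz.read_bus`,
`busz.sort_and_merge`, and the generators in `busz.synthetic`.

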