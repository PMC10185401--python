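"""Deterministic generators of sorted BUS fixtures.

The generator emulates the statistical structure of sorted single-cell
quantification output that the column codecs exploit: long runs of repeated
cell barcodes, UMIs non-decreasing within a cell, an equivalence-class
column with higher entropy (Zipf-skewed class frequencies), read counts that
are mostly one, and flags that are mostly zero.  It makes no attempt to
model barcode whitelists, sequencing error, or real transcriptome structure
— it produces the *shape* of the data, which is what the compression scheme
depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bus_io import BUS_DTYPE, BusHeader, sort_and_merge, write_bus

__all__ = ["SynthConfig", "generate_sorted_records", "generate_sorted_bus",
           "generate_adversarial_records", "ADVERSARIAL_KINDS"]


@dataclass
class SynthConfig:
    """Knobs for the sorted-BUS generator.

    Defaults sketch a modest droplet-style experiment: a few hundred cells,
    ~100 captured molecules per cell, 16 nt barcodes and 12 nt UMIs, a
    Zipf-skewed equivalence-class distribution, ~10% of counts above one and
    ~1% of flags set.
    """

    n_cells: int = 100
    mean_umis_per_cell: float = 100.0
    n_ecs: int = 1000
    ec_concentration: float = 1.2
    p_count_gt1: float = 0.1
    p_flag_set: float = 0.01
    bc_len: int = 16
    umi_len: int = 12
    seed: int = 20230502

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_ecs < 1:
            raise ValueError(f"n_ecs must be >= 1, got {self.n_ecs}")
        if self.mean_umis_per_cell < 0:
            raise ValueError("mean_umis_per_cell must be non-negative")
        for name in ("p_count_gt1", "p_flag_set"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("bc_len", "umi_len"):
            v = getattr(self, name)
            if not 1 <= v <= 32:
                raise ValueError(f"{name} must be in 1..32, got {v}")
        if self.n_cells > 4**self.bc_len:
            raise ValueError(
                f"{self.n_cells} distinct barcodes do not fit in {self.bc_len} nt"
            )


def _random_codes(rng: np.random.Generator, n: int, seq_len: int) -> np.ndarray:
    """n uniform 2-bit-encoded sequences of seq_len nucleotides, as u64."""
    hi = rng.integers(0, 1 << 32, size=n, dtype=np.uint64)
    lo = rng.integers(0, 1 << 32, size=n, dtype=np.uint64)
    codes = (hi << np.uint64(32)) | lo
    if seq_len < 32:
        codes &= np.uint64((1 << (2 * seq_len)) - 1)
    return codes


def _distinct_codes(rng: np.random.Generator, n: int, seq_len: int) -> np.ndarray:
    out = np.unique(_random_codes(rng, 2 * n + 16, seq_len))
    while len(out) < n:  # tiny sequence spaces may need more draws
        out = np.unique(np.concatenate([out, _random_codes(rng, 2 * n + 16, seq_len)]))
    return rng.permutation(out)[:n]


def generate_sorted_records(config: SynthConfig) -> tuple[BusHeader, np.ndarray]:
    """Generate a sorted, merged record array plus a matching header."""
    rng = np.random.default_rng(config.seed)
    barcodes = np.sort(_distinct_codes(rng, config.n_cells, config.bc_len))
    n_umis = rng.poisson(config.mean_umis_per_cell, size=config.n_cells)
    if n_umis.sum() == 0:
        n_umis[0] = 1  # never emit an empty experiment
    total = int(n_umis.sum())

    bc_col = np.repeat(barcodes, n_umis)
    umi_col = _random_codes(rng, total, config.umi_len)

    ranks = np.arange(1, config.n_ecs + 1, dtype=float)
    probs = ranks**-config.ec_concentration
    probs /= probs.sum()
    ec_col = rng.choice(config.n_ecs, size=total, p=probs).astype(np.int32)

    counts = np.ones(total, dtype=np.uint32)
    excess = rng.random(total) < config.p_count_gt1
    counts[excess] += rng.geometric(0.5, size=int(excess.sum())).astype(np.uint32)
    flags = (rng.random(total) < config.p_flag_set).astype(np.uint32)

    records = np.empty(total, dtype=BUS_DTYPE)
    records["barcode"] = bc_col
    records["umi"] = umi_col
    records["ec"] = ec_col
    records["count"] = counts
    records["flags"] = flags
    records["pad"] = 0
    header = BusHeader(version=1, bc_len=config.bc_len, umi_len=config.umi_len,
                       text=b"synthetic sorted BUS fixture")
    return header, sort_and_merge(records)


def generate_sorted_bus(config: SynthConfig, out) -> int:
    """Write a sorted, merged BUS file; returns the record count.

    Byte-identical output for identical configs (seed included).
    """
    header, records = generate_sorted_records(config)
    write_bus(header, records, out)
    return len(records)


ADVERSARIAL_KINDS = (
    "all_same_key",
    "strictly_increasing_everything",
    "max_values",
    "single_block_boundary_straddle",
)


def generate_adversarial_records(kind: str, seed: int = 0) -> np.ndarray:
    """Degenerate sorted fixtures that stress codec edge cases.

    ``all_same_key``: 100 copies of one (barcode, umi, ec) key, count 1 each
    (pre-merge).  ``strictly_increasing_everything``: every column strictly
    increases.  ``max_values``: fields at the top of their ranges (u64
    barcodes/UMIs, i32 max EC, u32 max count/flags).
    ``single_block_boundary_straddle``: one barcode owns 15 consecutive
    records so that, at block_size 10, its records span two blocks.
    """
    rng = np.random.default_rng(seed)
    if kind == "all_same_key":
        records = np.zeros(100, dtype=BUS_DTYPE)
        records["barcode"] = 7
        records["umi"] = 3
        records["ec"] = 2
        records["count"] = 1
        return records
    if kind == "strictly_increasing_everything":
        n = 64
        records = np.zeros(n, dtype=BUS_DTYPE)
        records["barcode"] = np.cumsum(rng.integers(1, 1000, n, dtype=np.uint64))
        records["umi"] = np.cumsum(rng.integers(1, 1000, n, dtype=np.uint64))
        records["ec"] = np.arange(n, dtype=np.int32) * 17
        records["count"] = np.arange(1, n + 1, dtype=np.uint32)
        records["flags"] = np.arange(n, dtype=np.uint32)
        return records
    if kind == "max_values":
        u64max = np.uint64(0xFFFF_FFFF_FFFF_FFFF)
        records = np.zeros(4, dtype=BUS_DTYPE)
        records["barcode"] = [u64max - np.uint64(1)] * 2 + [u64max] * 2
        records["umi"] = [u64max, u64max, u64max - np.uint64(1), u64max]
        records["ec"] = np.int32(2**31 - 1)
        records["count"] = np.uint32(2**32 - 1)
        records["flags"] = np.uint32(2**32 - 1)
        return records
    if kind == "single_block_boundary_straddle":
        parts = []
        for barcode, n in ((5, 5), (1000, 15), (2000, 5)):
            block = np.zeros(n, dtype=BUS_DTYPE)
            block["barcode"] = barcode
            block["umi"] = np.arange(n, dtype=np.uint64) * 3
            block["ec"] = rng.integers(0, 50, n, dtype=np.int32)
            block["count"] = 1
            parts.append(block)
        return sort_and_merge(np.concatenate(parts))
    raise ValueError(f"unknown adversarial kind {kind!r} (choose from {ADVERSARIAL_KINDS})")
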