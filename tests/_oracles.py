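"""Independent brute-force oracles used to cross-check the codecs.

Everything here works on plain Python ints and '0'/'1' text strings and
deliberately shares no code with the package's bit-level machinery.
"""

from __future__ import annotations

import itertools
import math


def zeckendorf_bits(n: int) -> str:
    """Greedy Zeckendorf codeword of n >= 1 as a bit string.

    Coefficients of F1=1, F2=2, F3=3, ... lowest index first, then a
    terminating 1.
    """
    assert n >= 1
    fibs = [1, 2]
    while fibs[-1] + fibs[-2] <= n:
        fibs.append(fibs[-1] + fibs[-2])
    m = max(i for i, f in enumerate(fibs) if f <= n)
    coeff = [0] * (m + 1)
    rem = n
    for i in range(m, -1, -1):
        if fibs[i] <= rem:
            coeff[i] = 1
            rem -= fibs[i]
    assert rem == 0
    return "".join(map(str, coeff)) + "1"


def fib_decode_bits(bits: str, pos: int) -> tuple[int, int]:
    """Decode one Zeckendorf codeword starting at ``pos``; return (value, new pos)."""
    fibs = [1, 2]
    value = 0
    i = 0
    prev = False
    while pos < len(bits):
        while i >= len(fibs):
            fibs.append(fibs[-1] + fibs[-2])
        bit = bits[pos] == "1"
        pos += 1
        if bit:
            if prev:
                return value, pos
            value += fibs[i]
            prev = True
        else:
            prev = False
        i += 1
    raise AssertionError("ran off the end of the bit string")


def rle_scan(values, target):
    """Run-scanning RLE oracle via itertools.groupby."""
    tokens = []
    for key, grp in itertools.groupby(values):
        run = len(list(grp))
        if key == target:
            tokens.append((target, run))
        else:
            tokens.extend([key] * run)
    return tokens


def naive_newpfd_encode(values, n_pfd: int, f: float) -> str:
    """Bit-string NewPFD encoder following the documented layout literally."""
    bits = []
    for s in range(0, len(values), n_pfd):
        block = list(values[s : s + n_pfd])
        k = min(block)
        offs = [x - k for x in block]
        rank = math.ceil(f * len(block))
        b = min(sorted(offs)[rank - 1].bit_length(), 32)
        exceptions = [(i, o >> b) for i, o in enumerate(offs) if o >> b]
        bits.append(zeckendorf_bits(b + 1))
        bits.append(zeckendorf_bits(k + 1))
        bits.append(zeckendorf_bits(len(exceptions) + 1))
        prev = 0
        for pos, high in exceptions:
            bits.append(zeckendorf_bits(pos - prev + 1))
            bits.append(zeckendorf_bits(high))
            prev = pos
        if b:
            for o in offs:
                bits.append(format(o & ((1 << b) - 1), f"0{b}b"))
    return "".join(bits)


def naive_newpfd_decode(bits: str, n: int, n_pfd: int) -> list[int]:
    out: list[int] = []
    pos = 0
    while len(out) < n:
        m = min(n - len(out), n_pfd)
        b, pos = fib_decode_bits(bits, pos)
        b -= 1
        k, pos = fib_decode_bits(bits, pos)
        k -= 1
        n_exc, pos = fib_decode_bits(bits, pos)
        n_exc -= 1
        exceptions = []
        prev = 0
        for _ in range(n_exc):
            gap, pos = fib_decode_bits(bits, pos)
            p = prev + gap - 1
            high, pos = fib_decode_bits(bits, pos)
            exceptions.append((p, high))
            prev = p
        vals = []
        for _ in range(m):
            if b:
                vals.append(k + int(bits[pos : pos + b], 2))
                pos += b
            else:
                vals.append(k)
        for p, high in exceptions:
            vals[p] += high << b
        out.extend(vals)
    return out


def bits_to_bytes(bits: str) -> bytes:
    padded = bits + "0" * (-len(bits) % 8)
    return bytes(int(padded[i : i + 8], 2) for i in range(0, len(padded), 8))


def bytes_to_bits(data: bytes, bit_length: int | None = None) -> str:
    s = "".join(format(byte, "08b") for byte in data)
    return s if bit_length is None else s[:bit_length]
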