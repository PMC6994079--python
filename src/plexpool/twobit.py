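"""UCSC .2bit genome file reading and writing.

Implements the published 2bit layout: signature 0x1A412743, version 0,
sequence index, then per-sequence records with N-block and mask-block lists
and packed 2-bit bases (T=0, C=1, A=2, G=3, first base in the high bits of
each byte).  Reading surfaces N-blocks as ``N`` and mask blocks as lowercase,
matching what a FASTA rendering of the same assembly would show.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterator

TWOBIT_SIGNATURE = 0x1A412743
_BITS = {"T": 0, "C": 1, "A": 2, "G": 3}
_BASES = "TCAG"


class TwoBitFormatError(ValueError):
    """Bad magic number or malformed 2bit structure."""


def _blocks(seq: str, predicate) -> list[tuple[int, int]]:
    """(start, size) runs of positions satisfying predicate."""
    out: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if predicate(ch):
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(seq) - start))
    return out


def write_2bit(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences (IUPAC text; non-ACGT stored as N-blocks, lowercase as
    mask blocks) to a 2bit file."""
    path = Path(path)
    names = list(sequences)
    with open(path, "wb") as fh:
        fh.write(struct.pack("<IIII", TWOBIT_SIGNATURE, 0, len(names), 0))
        # index: name length, name, offset placeholder
        index_pos: dict[str, int] = {}
        for name in names:
            raw = name.encode()
            fh.write(struct.pack("<B", len(raw)))
            fh.write(raw)
            index_pos[name] = fh.tell()
            fh.write(struct.pack("<I", 0))
        offsets: dict[str, int] = {}
        for name in names:
            offsets[name] = fh.tell()
            seq = sequences[name]
            upper = seq.upper()
            n_blocks = _blocks(upper, lambda c: c not in "ACGT")
            m_blocks = _blocks(seq, str.islower)
            fh.write(struct.pack("<I", len(seq)))
            fh.write(struct.pack("<I", len(n_blocks)))
            for start, _ in n_blocks:
                fh.write(struct.pack("<I", start))
            for _, size in n_blocks:
                fh.write(struct.pack("<I", size))
            fh.write(struct.pack("<I", len(m_blocks)))
            for start, _ in m_blocks:
                fh.write(struct.pack("<I", start))
            for _, size in m_blocks:
                fh.write(struct.pack("<I", size))
            fh.write(struct.pack("<I", 0))  # reserved
            packed = bytearray((len(seq) + 3) // 4)
            for i, ch in enumerate(upper):
                code = _BITS.get(ch, 0)  # N-blocks mark the true identity
                packed[i // 4] |= code << (2 * (3 - i % 4))
            fh.write(bytes(packed))
        for name in names:
            fh.seek(index_pos[name])
            fh.write(struct.pack("<I", offsets[name]))


def is_2bit(path: str | Path) -> bool:
    try:
        with open(path, "rb") as fh:
            head = fh.read(4)
    except OSError:
        return False
    if len(head) < 4:
        return False
    (sig,) = struct.unpack("<I", head)
    if sig == TWOBIT_SIGNATURE:
        return True
    (sig_be,) = struct.unpack(">I", head)
    return sig_be == TWOBIT_SIGNATURE


def read_2bit(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) in file order; N-blocks as N, mask blocks
    lowercase."""
    with open(path, "rb") as fh:
        head = fh.read(16)
        if len(head) < 16:
            raise TwoBitFormatError(f"{path}: truncated header")
        for endian in ("<", ">"):
            sig, version, count, _reserved = struct.unpack(endian + "IIII", head)
            if sig == TWOBIT_SIGNATURE:
                break
        else:
            raise TwoBitFormatError(f"{path}: bad 2bit signature")
        if version != 0:
            raise TwoBitFormatError(f"{path}: unsupported 2bit version {version}")

        def u32() -> int:
            (v,) = struct.unpack(endian + "I", fh.read(4))
            return v

        entries: list[tuple[str, int]] = []
        for _ in range(count):
            (nlen,) = struct.unpack("<B", fh.read(1))
            name = fh.read(nlen).decode()
            entries.append((name, u32()))
        for name, offset in entries:
            fh.seek(offset)
            size = u32()
            n_count = u32()
            n_starts = [u32() for _ in range(n_count)]
            n_sizes = [u32() for _ in range(n_count)]
            m_count = u32()
            m_starts = [u32() for _ in range(m_count)]
            m_sizes = [u32() for _ in range(m_count)]
            u32()  # reserved
            packed = fh.read((size + 3) // 4)
            chars = []
            for i in range(size):
                byte = packed[i // 4]
                chars.append(_BASES[(byte >> (2 * (3 - i % 4))) & 3])
            seq = bytearray("".join(chars), "ascii")
            for start, blen in zip(n_starts, n_sizes):
                seq[start:start + blen] = b"N" * blen
            text = seq.decode()
            if m_count:
                buf = list(text)
                for start, blen in zip(m_starts, m_sizes):
                    buf[start:start + blen] = (
                        c.lower() for c in buf[start:start + blen]
                    )
                text = "".join(buf)
            yield name, text
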