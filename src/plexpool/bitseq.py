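"""Bit-plane primer encodings and base-level bonding tests.

Primer–primer complementarity is evaluated with bit-parallel operations on
arbitrary-precision integers used as bit vectors.  Each primer is packed into
two planes (plus a validity mask): the A|T plane marks bases in {A, T} and the
G|T plane marks bases in {G, T}, so that two aligned bases form a Watson–Crick
bond iff their A|T bits are equal and their G|T bits differ::

    bonds = XNOR(at1, at2) & XOR(gt1, gt2) & valid1 & valid2

Degenerate (IUPAC) primers use four planes R_A, R_C, R_G, R_T, one per base a
position *might* be; a position bonds when some base choice on each side is
complementary::

    bonds = (RA1 & RT2) | (RC1 & RG2) | (RG1 & RC2) | (RT1 & RA2)

Bit convention: bit ``i`` of a plane is base ``i`` counted from the 5' end.
In all bonding functions the second primer is presented antiparallel: its
planes are bit-reversed so that offset 0 juxtaposes primer 1's 5' end with
primer 2's 3' end, and the offset slides primer 2 rightwards along primer 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "H": "ACT", "B": "CGT", "V": "ACG", "D": "AGT", "N": "ACGT",
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "M": "K", "K": "M", "S": "S", "W": "W",
    "H": "D", "B": "V", "V": "B", "D": "H", "N": "N",
}

WATSON_CRICK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

MAX_PRIMER_LEN = 128


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class DegenerateBaseError(ValueError):
    """Exact encoding was requested for a sequence with degenerate bases."""


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - IUPAC_SETS.keys()
    if bad:
        raise AlphabetError(
            f"non-IUPAC characters {sorted(bad)} in sequence {sequence!r}"
        )


def _revbits(x: int, n: int) -> int:
    """Reverse the low n bits of x."""
    r = 0
    for _ in range(n):
        r = (r << 1) | (x & 1)
        x >>= 1
    return r


@dataclass(frozen=True)
class EncodedPrimer:
    """Three-plane (exact ACGT) bit encoding of a primer."""

    at_plane: int
    gt_plane: int
    valid_bits: int
    length: int

    @property
    def sequence(self) -> str:
        out = []
        for i in range(self.length):
            at = (self.at_plane >> i) & 1
            gt = (self.gt_plane >> i) & 1
            out.append({(1, 0): "A", (0, 0): "C", (0, 1): "G", (1, 1): "T"}[(at, gt)])
        return "".join(out)


@dataclass(frozen=True)
class DegenerateEncodedPrimer:
    """Four-plane (IUPAC) bit encoding: one plane per base a position might be."""

    ra: int
    rc: int
    rg: int
    rt: int
    length: int

    @property
    def valid_bits(self) -> int:
        return self.ra | self.rc | self.rg | self.rt


@dataclass(frozen=True)
class BondPattern:
    """Bonded positions of one antiparallel juxtaposition of two primers.

    ``bonds`` bit ``c`` refers to alignment column ``c`` (columns are indexed
    from the leftmost position occupied by either primer at this offset).
    """

    bonds: int
    width: int

    @property
    def count(self) -> int:
        return self.bonds.bit_count()


def encode_exact(sequence: str) -> EncodedPrimer:
    """Encode an ACGT-only sequence into A|T and G|T planes.

    Raises DegenerateBaseError if the sequence has IUPAC wildcards (callers
    should fall back to :func:`encode_degenerate`).
    """
    _check_alphabet(sequence)
    if set(sequence) - set("ACGT"):
        raise DegenerateBaseError(
            f"sequence {sequence!r} contains degenerate bases; "
            "use encode_degenerate"
        )
    at = gt = 0
    for i, base in enumerate(sequence):
        if base in "AT":
            at |= 1 << i
        if base in "GT":
            gt |= 1 << i
    return EncodedPrimer(at, gt, (1 << len(sequence)) - 1, len(sequence))


def encode_degenerate(sequence: str) -> DegenerateEncodedPrimer:
    """Encode an IUPAC sequence into R_A/R_C/R_G/R_T possibility planes."""
    _check_alphabet(sequence)
    ra = rc = rg = rt = 0
    for i, base in enumerate(sequence):
        choices = IUPAC_SETS[base]
        if "A" in choices:
            ra |= 1 << i
        if "C" in choices:
            rc |= 1 << i
        if "G" in choices:
            rg |= 1 << i
        if "T" in choices:
            rt |= 1 << i
    return DegenerateEncodedPrimer(ra, rc, rg, rt, len(sequence))


def upgrade(e: EncodedPrimer) -> DegenerateEncodedPrimer:
    """Convert a three-plane encoding to the equivalent four-plane form."""
    a = e.at_plane & ~e.gt_plane & e.valid_bits
    c = ~e.at_plane & ~e.gt_plane & e.valid_bits
    g = ~e.at_plane & e.gt_plane & e.valid_bits
    t = e.at_plane & e.gt_plane & e.valid_bits
    return DegenerateEncodedPrimer(a, c, g, t, e.length)


def offsets(len1: int, len2: int) -> range:
    """All antiparallel juxtapositions with at least one aligned column."""
    return range(-(len2 - 1), len1) if len1 and len2 else range(0)


def bond_pattern(p1: EncodedPrimer, p2: EncodedPrimer, offset: int) -> BondPattern:
    """Bond pattern of p1 (5'->3') against antiparallel p2 shifted by offset."""
    n2 = p2.length
    at2 = _revbits(p2.at_plane, n2)
    gt2 = _revbits(p2.gt_plane, n2)
    v2 = (1 << n2) - 1
    s1, s2 = (0, offset) if offset >= 0 else (-offset, 0)
    both = (p1.valid_bits << s1) & (v2 << s2)
    bonds = ~((p1.at_plane << s1) ^ (at2 << s2)) & ((p1.gt_plane << s1) ^ (gt2 << s2)) & both
    width = max(p1.length + s1, n2 + s2)
    return BondPattern(bonds, width)


def bond_pattern_degenerate(
    p1: DegenerateEncodedPrimer, p2: DegenerateEncodedPrimer, offset: int
) -> BondPattern:
    """Degenerate bond pattern: a column bonds if the base sets admit a
    complementary choice on each side."""
    n2 = p2.length
    ra2 = _revbits(p2.ra, n2)
    rc2 = _revbits(p2.rc, n2)
    rg2 = _revbits(p2.rg, n2)
    rt2 = _revbits(p2.rt, n2)
    s1, s2 = (0, offset) if offset >= 0 else (-offset, 0)
    bonds = (
        ((p1.ra << s1) & (rt2 << s2))
        | ((p1.rc << s1) & (rg2 << s2))
        | ((p1.rg << s1) & (rc2 << s2))
        | ((p1.rt << s1) & (ra2 << s2))
    )
    width = max(p1.length + s1, n2 + s2)
    return BondPattern(bonds, width)


def aligned_columns(
    seq1: str, seq2: str, offset: int
) -> Iterator[tuple[int, int, str, str]]:
    """Yield (column, p1_index, p1_base, p2_base) for aligned positions.

    p2 is presented antiparallel (3'->5'), consistent with the bit-plane
    bonding functions: p2 position j (counted from its 3' end) sits at
    column j + offset, p1 position i at column i.
    """
    n1, n2 = len(seq1), len(seq2)
    s1, s2 = (0, offset) if offset >= 0 else (-offset, 0)
    lo = max(s1, s2)
    hi = min(n1 + s1, n2 + s2)
    for c in range(lo, hi):
        i = c - s1
        j = c - s2
        yield c, i, seq1[i], seq2[n2 - 1 - j]


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    _check_alphabet(sequence)
    return "".join(IUPAC_COMPLEMENT[b] for b in reversed(sequence))


class ExpansionCapError(ValueError):
    """Degenerate expansion would exceed the configured variant cap."""


DEFAULT_EXPANSION_CAP = 4096


def expand_degenerate(
    sequence: str, cap: int = DEFAULT_EXPANSION_CAP, name: str = ""
) -> list[str]:
    """Cartesian expansion of a degenerate sequence into concrete ACGT strings.

    Deterministic order: per position A<C<G<T, leftmost position varying
    slowest.  Raises ExpansionCapError when the variant count exceeds ``cap``.
    """
    _check_alphabet(sequence)
    count = 1
    for base in sequence:
        count *= len(IUPAC_SETS[base])
    if count > cap:
        label = f" for primer {name}" if name else ""
        raise ExpansionCapError(
            f"degenerate expansion{label} yields {count} variants (cap {cap})"
        )
    return ["".join(p) for p in product(*(sorted(IUPAC_SETS[b]) for b in sequence))]
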