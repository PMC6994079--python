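"""Index-free simultaneous mapping of all primers onto a genome.

Instead of building a genome index, every primer (and, for degenerate
primers, every concrete base combination) plus its reverse complement is
packed into a 2-bit window of its last ≤32 bases with a validity mask.  The
last *N* genome bases seen — *N* being the length of the shortest primer —
form a fixed-length key looked up by binary search at each position; only on
a key hit is the variant's full window verified.  Primers longer than 32
bases are matched by their last 32 bases only and flagged with a warning.

Primer-site hits become "events" in a positional sweep along each
chromosome: a forward-role hit on the + strand (or reverse-role hit on the
+ strand for negative-strand-first products) opens a candidate amplicon,
closed by the partner primer's site in convergent orientation within the
user's maximum amplicon length.  Overlapping amplicons on the same
chromosome are reported and their primer pairs can have their mutual
interaction entries saturated so the partitioner must separate them.

Coordinates are 0-based half-open internally; report helpers render 1-based
inclusive.  Soft-masked (lowercase) genome bases match as their uppercase
selves; windows containing any non-ACGT base never match.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .bitseq import expand_degenerate, reverse_complement, DEFAULT_EXPANSION_CAP
from .hybridization import InteractionTable
from .primer_io import PrimerSet
from .pooling import RANGE_SATURATION
from .twobit import is_2bit, read_2bit, TwoBitFormatError

logger = logging.getLogger(__name__)

WINDOW_BASES = 32  # genome search window: last 32 bases of each variant
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class GenomeFormatError(ValueError):
    pass


def read_genome(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (chromosome name, sequence) from a .2bit or FASTA file."""
    path = Path(path)
    if not path.exists():
        raise GenomeFormatError(f"genome file not found: {path}")
    if path.stat().st_size == 0:
        raise GenomeFormatError(f"genome file is empty: {path}")
    if is_2bit(path):
        try:
            yield from read_2bit(path)
        except TwoBitFormatError as exc:
            raise GenomeFormatError(str(exc)) from exc
        return
    with open(path) as fh:
        first = fh.read(1)
    if first != ">":
        raise GenomeFormatError(
            f"{path}: neither a 2bit file nor FASTA (no leading '>')")
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        yield rec.id, str(rec.seq)
    if n == 0:
        raise GenomeFormatError(f"{path}: no FASTA records")


def _pack(seq: str) -> tuple[int, int]:
    """(value, mask) of a ≤32-base ACGT string, leftmost base in the highest
    occupied 2 bits."""
    value = 0
    for base in seq:
        value = (value << 2) | _CODE[base]
    return value, (1 << (2 * len(seq))) - 1


@dataclass(frozen=True)
class Variant:
    primer_name: str
    pair_id: int | None
    role: str       # forward | reverse | unknown
    strand: str     # + if the variant is the primer as written, - if revcomp
    window: str     # last <=32 bases of the scanned-orientation sequence
    full_value: int
    full_mask: int
    fixed_key: int
    primer_len: int


@dataclass
class VariantIndex:
    variants: list[Variant]
    n: int                     # fixed-key length = shortest primer, <=32
    sorted_keys: list[int]
    by_key: dict[int, list[Variant]]
    long_primers: list[str] = field(default_factory=list)


def build_variant_index(pset: PrimerSet,
                        cap: int = DEFAULT_EXPANSION_CAP) -> VariantIndex:
    """Expand and pack every primer (untagged) and its reverse complement."""
    primers: list[tuple[str, int | None, str, str]] = []
    for pair in pset.pairs:
        primers.append((pair.forward.name, pair.index, "forward",
                        pair.forward.sequence))
        primers.append((pair.reverse.name, pair.index, "reverse",
                        pair.reverse.sequence))
    for rec in pset.unpaired:
        primers.append((rec.name, None, "unknown", rec.sequence))
    if not primers:
        raise ValueError("no primers to index")
    n = min(min(len(seq) for *_, seq in primers), WINDOW_BASES)
    long_primers = sorted({name for name, _, _, seq in primers
                           if len(seq) > WINDOW_BASES})
    for name in long_primers:
        logger.warning(
            "primer %s is longer than %d bases; only its last %d bases are "
            "used for genome matching", name, WINDOW_BASES, WINDOW_BASES)
    variants: list[Variant] = []
    seen: set[tuple[str, str, str]] = set()  # degeneracy outside the window
    for name, pair_id, role, seq in primers:
        for concrete in expand_degenerate(seq, cap=cap, name=name):
            for strand, oriented in (("+", concrete),
                                     ("-", reverse_complement(concrete))):
                window = oriented[-WINDOW_BASES:]
                if (name, strand, window) in seen:
                    continue
                seen.add((name, strand, window))
                value, mask = _pack(window)
                key, _ = _pack(window[-n:])
                variants.append(Variant(name, pair_id, role, strand, window,
                                        value, mask, key, len(seq)))
    by_key: dict[int, list[Variant]] = {}
    for v in variants:
        by_key.setdefault(v.fixed_key, []).append(v)
    return VariantIndex(variants=variants, n=n,
                        sorted_keys=sorted(by_key), by_key=by_key,
                        long_primers=long_primers)


@dataclass(frozen=True)
class GenomeHit:
    primer_name: str
    pair_id: int | None
    role: str
    chromosome: str
    start: int   # 0-based half-open interval of the matched window
    end: int
    strand: str

    @property
    def pos3(self) -> int:
        """0-based coordinate of the 3'-most matched base of the primer."""
        return self.end - 1 if self.strand == "+" else self.start


def scan_chromosome(name: str, seq: str, index: VariantIndex) -> list[GenomeHit]:
    """All primer-variant matches in one chromosome, sorted by position.

    The last-N-bases key at each position is binary-searched in the sorted
    key list; on a hit, each candidate variant's full window is verified.
    """
    n = index.n
    upper = seq.upper()
    length = len(upper)
    if length < n:
        return []
    arr = np.frombuffer(upper.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(length, dtype=np.uint64)
    valid = np.zeros(length, dtype=bool)
    for base, code in _CODE.items():
        m = arr == ord(base)
        codes[m] = code
        valid |= m
    # rolling key over windows [t, t+n): leftmost base in the highest bits
    key = np.zeros(length - n + 1, dtype=np.uint64)
    for j in range(n):
        key = (key << np.uint64(2)) | codes[j:length - n + 1 + j]
    bad = np.cumsum(np.concatenate(([0], (~valid).astype(np.int64))))
    window_ok = (bad[n:] - bad[:-n]) == 0
    keyset = np.fromiter(index.sorted_keys, dtype=np.uint64,
                         count=len(index.sorted_keys))
    candidate = np.isin(key, keyset) & window_ok
    hits: list[GenomeHit] = []
    for t in np.nonzero(candidate)[0]:
        end = int(t) + n  # window [t, t+n) ends here
        for variant in index.by_key[int(key[t])]:
            w = len(variant.window)
            start = end - w
            if start < 0:
                continue
            if not valid[start:end].all():
                continue
            if upper[start:end] == variant.window:
                hits.append(GenomeHit(variant.primer_name, variant.pair_id,
                                      variant.role, name, start, end,
                                      variant.strand))
    hits.sort(key=lambda h: (h.start, h.end, h.primer_name, h.strand))
    return hits


def scan_genome(genome: Iterable[tuple[str, str]],
                index: VariantIndex) -> list[GenomeHit]:
    hits: list[GenomeHit] = []
    for name, seq in genome:
        chrom_hits = scan_chromosome(name, seq, index)
        logger.info("scanned %s (%d bases): %d primer sites", name, len(seq),
                    len(chrom_hits))
        hits.extend(chrom_hits)
    return hits


@dataclass(frozen=True)
class Amplicon:
    pair_id: int
    chromosome: str
    start: int   # 0-based half-open, primers included
    end: int
    orientation: str  # positive-strand-first | negative-strand-first

    @property
    def length(self) -> int:
        return self.end - self.start

    def region_1based(self) -> str:
        return f"{self.chromosome}:{self.start + 1}-{self.end}"


def find_amplicons(hits: list[GenomeHit], max_len: int) -> list[Amplicon]:
    """Pair convergent primer-site events within ``max_len``.

    A + strand forward site opens a positive-strand-first amplicon closed by
    the pair's reverse site on the − strand; a + strand reverse site opens
    the negative-strand-first case closed by the forward site on −.  Each
    opening event takes the nearest in-limit closing event (the product PCR
    would favour); one pair may yield several amplicons at distinct loci.
    """
    by_pair_chrom: dict[tuple[int, str], list[GenomeHit]] = {}
    for h in hits:
        if h.pair_id is None:
            continue
        by_pair_chrom.setdefault((h.pair_id, h.chromosome), []).append(h)
    amplicons: set[Amplicon] = set()
    for (pair_id, chrom), group in by_pair_chrom.items():
        group.sort(key=lambda h: (h.start, h.end))
        for opener_role, closer_role, orientation in (
                ("forward", "reverse", "positive-strand-first"),
                ("reverse", "forward", "negative-strand-first")):
            openers = [h for h in group
                       if h.role == opener_role and h.strand == "+"]
            closers = [h for h in group
                       if h.role == closer_role and h.strand == "-"]
            for o in openers:
                best = None
                for c in closers:
                    if c.start < o.start:
                        continue
                    if c.end - o.start > max_len:
                        continue
                    if best is None or c.end < best.end:
                        best = c
                if best is not None and best.end > o.start:
                    amplicons.add(Amplicon(pair_id, chrom, o.start, best.end,
                                           orientation))
    return sorted(amplicons,
                  key=lambda a: (a.chromosome, a.start, a.end, a.pair_id))


@dataclass
class OverlapReport:
    overlaps: list[tuple[Amplicon, Amplicon, tuple[int, int]]]
    unmatched_pairs: list[int]

    def overlapping_pair_ids(self) -> set[tuple[int, int]]:
        return {tuple(sorted((a.pair_id, b.pair_id)))
                for a, b, _ in self.overlaps if a.pair_id != b.pair_id}


def detect_overlaps(amplicons: list[Amplicon],
                    all_pair_ids: Iterable[int] | None = None) -> OverlapReport:
    """Report every same-chromosome amplicon pair with intersecting
    intervals (positional sweep), plus pairs with no amplicon at all."""
    overlaps: list[tuple[Amplicon, Amplicon, tuple[int, int]]] = []
    by_chrom: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom_amps in by_chrom.values():
        chrom_amps.sort(key=lambda a: (a.start, a.end))
        active: list[Amplicon] = []
        for a in chrom_amps:
            active = [x for x in active if x.end > a.start]
            for x in active:
                shared = (max(x.start, a.start), min(x.end, a.end))
                overlaps.append((x, a, shared))
            active.append(a)
    matched = {a.pair_id for a in amplicons}
    unmatched = []
    if all_pair_ids is not None:
        unmatched = sorted(set(all_pair_ids) - matched)
        for pid in unmatched:
            logger.warning(
                "primer pair %d formed no amplicon within the length limit; "
                "overlap with other pairs cannot be verified", pid)
    return OverlapReport(overlaps=overlaps, unmatched_pairs=unmatched)


def overlap_constraints(report: OverlapReport, table: InteractionTable,
                        pset: PrimerSet) -> InteractionTable:
    """Saturate the four cross-primer entries of every overlapping amplicon
    pair so the partitioner must keep them apart.  Returns a new table; the
    input (with the original values) is untouched."""
    out = InteractionTable(mode=table.mode, results=dict(table.results))
    pair_by_id = {p.index: p for p in pset.pairs}
    saturated_value = (float(RANGE_SATURATION) if table.mode == "score"
                       else -RANGE_SATURATION / 2.0)
    for pid_a, pid_b in report.overlapping_pair_ids():
        pa, pb = pair_by_id[pid_a], pair_by_id[pid_b]
        for x in (pa.forward, pa.reverse):
            for y in (pb.forward, pb.reverse):
                old = out.get(x.name, y.name)
                if table.mode == "score":
                    out.put(replace(old, best_score=int(saturated_value)))
                else:
                    out.put(replace(old, best_dg=saturated_value))
    return out


def binary_search_key(sorted_keys: list[int], key: int) -> bool:
    """Membership test on the sorted fixed-key list (the scan's first-stage
    lookup, exposed for testing)."""
    i = bisect_left(sorted_keys, key)
    return i < len(sorted_keys) and sorted_keys[i] == key


def amplicons_to_bed(amplicons: list[Amplicon], pset: PrimerSet) -> str:
    names = {p.index: p.amplicon_name for p in pset.pairs}
    lines = []
    for a in amplicons:
        strand = "+" if a.orientation == "positive-strand-first" else "-"
        lines.append(f"{a.chromosome}\t{a.start}\t{a.end}"
                     f"\t{names.get(a.pair_id, a.pair_id)}\t0\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def overlap_report_text(report: OverlapReport, pset: PrimerSet) -> str:
    names = {p.index: p.amplicon_name for p in pset.pairs}
    lines = [f"{len(report.overlaps)} overlapping amplicon pair(s):"]
    for a, b, (lo, hi) in report.overlaps:
        lines.append(
            f"  {names.get(a.pair_id, a.pair_id)} {a.region_1based()} overlaps "
            f"{names.get(b.pair_id, b.pair_id)} {b.region_1based()} "
            f"shared {lo + 1}-{hi}")
    if report.unmatched_pairs:
        lines.append("WARNING: pairs with no amplicon found:")
        for pid in report.unmatched_pairs:
            lines.append(f"  {names.get(pid, pid)}")
    return "\n".join(lines)
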