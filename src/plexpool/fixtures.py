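"""Deterministic synthetic primer sets, toy genomes and interaction tables.

Every generator is seeded and byte-reproducible, and returns exact ground
truth (planted primer sites, expected amplicons and overlaps, known optimal
partitions) so each pipeline stage can be tested without downloads.
Background genome sequence is uniform over ACGT with an optional N block;
generation re-draws (bounded retries) whenever the background would contain
an unplanned occurrence of any primer or its reverse complement.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .bitseq import expand_degenerate, reverse_complement
from .hybridization import InteractionResult, InteractionTable
from .primer_io import PrimerPair, PrimerRecord, PrimerSet, parse_primer_fasta
from .twobit import write_2bit
from .genomescan import Amplicon, GenomeHit

DEGENERATE_CODES = "RYMKSWHBVDN"


@dataclass
class PlantedAmplicon:
    pair_id: int
    chromosome: str
    start: int
    length: int
    orientation: str = "positive-strand-first"
    overlap_group: int | None = None


@dataclass
class FixtureSpec:
    seed: int = 0
    n_pairs: int = 4
    primer_len: tuple[int, int] = (18, 25)
    n_degenerate: int = 0
    with_tags: bool = False
    genome_len: int = 5000
    chromosomes: tuple[str, ...] = ("chr1",)
    n_block: tuple[int, int] | None = None  # (start, length) of an N run
    planted: list[PlantedAmplicon] = field(default_factory=list)
    max_retries: int = 50


def _random_primer(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_primer_set(spec: FixtureSpec) -> PrimerSet:
    """Random primer pairs named by the F/R last-letter convention.

    ``n_degenerate`` primers (taken in order) get one IUPAC wildcard at a
    random interior position; ``with_tags`` adds a tagF/tagR record pair.
    """
    rng = random.Random(spec.seed)
    records: list[str] = []
    if spec.with_tags:
        records.append(">tagF\n" + _random_primer(rng, 22))
        records.append(">tagR\n" + _random_primer(rng, 22))
    degenerate_left = spec.n_degenerate
    for i in range(spec.n_pairs):
        for suffix in ("F", "R"):
            length = rng.randint(*spec.primer_len)
            seq = _random_primer(rng, length)
            if degenerate_left > 0:
                pos = rng.randrange(1, length - 1)
                seq = seq[:pos] + rng.choice(DEGENERATE_CODES) + seq[pos + 1:]
                degenerate_left -= 1
            records.append(f">AMP{i:03d}_ex1-{suffix}\n{seq}")
    return parse_primer_fasta("\n".join(records) + "\n")


def default_layout(spec: FixtureSpec, pset: PrimerSet,
                   max_len: int = 400) -> list[PlantedAmplicon]:
    """Evenly spaced non-overlapping amplicons on the first chromosome."""
    rng = random.Random(spec.seed + 1)
    gap = spec.genome_len // (len(pset.pairs) + 1)
    planted = []
    for pair in pset.pairs:
        min_len = (len(pair.forward.sequence) + len(pair.reverse.sequence))
        length = rng.randint(min_len + 20, min(max_len, gap - 10))
        planted.append(PlantedAmplicon(pair.index, spec.chromosomes[0],
                                       gap * (pair.index + 1) - length // 2,
                                       length))
    return planted


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    expected_hits: list[GenomeHit]
    expected_amplicons: list[Amplicon]
    expected_overlaps: set[tuple[int, int]]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        return path

    def write_2bit(self, path: str | Path) -> Path:
        path = Path(path)
        write_2bit(self.sequences, path)
        return path


def _concrete(rng: random.Random, seq: str) -> str:
    variants = expand_degenerate(seq)
    return variants[rng.randrange(len(variants))]


def make_genome(spec: FixtureSpec, pset: PrimerSet,
                planted: list[PlantedAmplicon] | None = None) -> SyntheticGenome:
    """Plant each requested amplicon's primer sites in random background.

    Positive-strand-first plants the forward primer at the amplicon start
    and the reverse primer's reverse complement at its end (roles swap for
    negative-strand-first).  Degenerate primers are planted as one concrete
    expansion.  Ground truth (hits, amplicons, overlaps) is derived from the
    layout, not re-measured.
    """
    if planted is None:
        planted = spec.planted or default_layout(spec, pset)
    pair_by_id = {p.index: p for p in pset.pairs}
    all_window_seqs: set[str] = set()
    for rec in pset.records():
        for concrete in expand_degenerate(rec.sequence):
            all_window_seqs.add(concrete)
            all_window_seqs.add(reverse_complement(concrete))

    for attempt in range(spec.max_retries):
        rng = random.Random(spec.seed * 1009 + attempt)
        sequences: dict[str, str] = {}
        expected_hits: list[GenomeHit] = []
        expected_amplicons: list[Amplicon] = []
        for chrom in spec.chromosomes:
            buf = list(_random_primer(rng, spec.genome_len))
            if spec.n_block is not None:
                start, length = spec.n_block
                buf[start:start + length] = "N" * length
            for pa in (p for p in planted if p.chromosome == chrom):
                pair = pair_by_id[pa.pair_id]
                fwd = _concrete(rng, pair.forward.sequence)
                rev = _concrete(rng, pair.reverse.sequence)
                if pa.orientation == "positive-strand-first":
                    left, right = fwd, reverse_complement(rev)
                    left_rec, right_rec = pair.forward, pair.reverse
                else:
                    left, right = rev, reverse_complement(fwd)
                    left_rec, right_rec = pair.reverse, pair.forward
                end = pa.start + pa.length
                if pa.start < 0 or end > spec.genome_len:
                    raise ValueError(
                        f"planted amplicon for pair {pa.pair_id} outside genome")
                if pa.length < len(left) + len(right):
                    raise ValueError(
                        f"planted amplicon for pair {pa.pair_id} shorter than "
                        "its two primers")
                buf[pa.start:pa.start + len(left)] = left
                buf[end - len(right):end] = right
                expected_hits.append(GenomeHit(
                    left_rec.name, pair.index, left_rec.role, chrom,
                    pa.start, pa.start + len(left), "+"))
                expected_hits.append(GenomeHit(
                    right_rec.name, pair.index, right_rec.role, chrom,
                    end - len(right), end, "-"))
                expected_amplicons.append(Amplicon(
                    pair.index, chrom, pa.start, end, pa.orientation))
            sequences[chrom] = "".join(buf)

        # reject backgrounds with unplanned primer occurrences
        expected_locs = {
            (h.chromosome, h.start,
             sequences[h.chromosome][h.start:h.end])
            for h in expected_hits
        }
        clean = True
        for chrom, seq in sequences.items():
            for probe in all_window_seqs:
                at = seq.find(probe)
                while at != -1:
                    if (chrom, at, probe) not in expected_locs:
                        clean = False
                        break
                    at = seq.find(probe, at + 1)
                if not clean:
                    break
            if not clean:
                break
        if clean:
            expected_hits.sort(key=lambda h: (h.chromosome, h.start, h.end,
                                              h.primer_name, h.strand))
            expected_amplicons.sort(
                key=lambda a: (a.chromosome, a.start, a.end, a.pair_id))
            groups: dict[int, list[int]] = {}
            for pa in planted:
                if pa.overlap_group is not None:
                    groups.setdefault(pa.overlap_group, []).append(pa.pair_id)
            overlaps = {
                tuple(sorted((a, b)))
                for members in groups.values()
                for ai, a in enumerate(members) for b in members[ai + 1:]
            }
            return SyntheticGenome(sequences, expected_hits,
                                   expected_amplicons, overlaps)
    raise RuntimeError(
        f"could not place primers without collisions in {spec.max_retries} "
        "attempts; enlarge the genome or shorten the primers")


def make_interaction_table(
    spec: FixtureSpec,
    cliques: list[tuple[list[int], int]] | None = None,
    mode: str = "score",
) -> tuple[PrimerSet, InteractionTable]:
    """Primer set plus a planted block-structured interaction table.

    ``cliques`` is a list of (pair_ids, range): every cross-pair primer
    interaction inside a clique gets that range; everything else 0.
    Random off-structure noise is deliberately absent so brute-force optima
    are easy to reason about.
    """
    pset = make_primer_set(spec)
    table = InteractionTable(mode=mode)
    recs = pset.records()
    pair_of = {}
    for pair in pset.pairs:
        pair_of[pair.forward.name] = pair.index
        pair_of[pair.reverse.name] = pair.index
    clique_of: dict[int, tuple[int, int]] = {}
    for ci, (members, rng_val) in enumerate(cliques or []):
        for pid in members:
            clique_of[pid] = (ci, rng_val)
    for i, a in enumerate(recs):
        for b in recs[i:]:
            pa, pb = pair_of.get(a.name), pair_of.get(b.name)
            value = 0
            if (pa is not None and pb is not None and pa != pb
                    and pa in clique_of and pb in clique_of
                    and clique_of[pa][0] == clique_of[pb][0]):
                value = clique_of[pa][1]
            if mode == "score":
                table.put(InteractionResult(a.name, b.name, best_score=value))
            else:
                table.put(InteractionResult(a.name, b.name,
                                            best_dg=-value / 2.0))
    return pset, table
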