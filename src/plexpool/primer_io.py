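"""Primer list input/output.

Primer lists are plain FASTA.  A forward/reverse pair shares a name except
for its last letter (``F`` vs ``R``, case-insensitive): ``ARID1A_ex1-F`` and
``ARID1A_ex1-R`` form the pair of amplicon ``ARID1A_ex1-``.  Records named
``tagF``/``tagR`` (case-insensitive) are 5' common sequences (index/barcode
tags) applied to every forward/reverse primer for hybridization analysis but
never for genome scanning.  Sequences may be mixed case with embedded
whitespace and may use IUPAC degenerate codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bitseq import IUPAC_SETS, MAX_PRIMER_LEN

logger = logging.getLogger(__name__)


class PrimerParseError(ValueError):
    """Malformed primer list (bad characters, duplicates, empty file...)."""


@dataclass(frozen=True)
class PrimerRecord:
    """One primer: normalized IUPAC sequence 5'->3' plus an optional 5' tag."""

    name: str
    sequence: str
    role: str  # forward | reverse | tag-forward | tag-reverse | unknown
    tag: str = ""

    @property
    def full_sequence(self) -> str:
        """Tagged sequence used in hybridization analysis."""
        return self.tag + self.sequence

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class PrimerPair:
    amplicon_name: str
    forward: PrimerRecord
    reverse: PrimerRecord
    index: int


@dataclass
class PrimerSet:
    pairs: list[PrimerPair] = field(default_factory=list)
    tag_forward: PrimerRecord | None = None
    tag_reverse: PrimerRecord | None = None
    unpaired: list[PrimerRecord] = field(default_factory=list)

    def records(self) -> list[PrimerRecord]:
        """All analysable primers (pairs first, in input order, then unpaired)."""
        out: list[PrimerRecord] = []
        for pair in self.pairs:
            out.append(pair.forward)
            out.append(pair.reverse)
        out.extend(self.unpaired)
        return out

    def summary(self) -> dict[str, int]:
        recs = self.records()
        lengths = [len(r.sequence) for r in recs]
        tag_lens = [
            len(t.sequence)
            for t in (self.tag_forward, self.tag_reverse)
            if t is not None
        ]
        return {
            "n_primers": len(recs),
            "n_pairs": len(self.pairs),
            "min_length": min(lengths, default=0),
            "max_length": max(lengths, default=0),
            "max_tag_length": max(tag_lens, default=0),
            "max_tagged_length": max((len(r) for r in recs), default=0),
        }


def _normalize(name: str, raw: str) -> str:
    seq = "".join(raw.split()).upper()
    bad = set(seq) - IUPAC_SETS.keys()
    if bad:
        raise PrimerParseError(
            f"record {name!r}: non-IUPAC characters {sorted(bad)}"
        )
    if not seq:
        raise PrimerParseError(f"record {name!r}: empty sequence")
    return seq


def parse_primer_fasta(text: str) -> PrimerSet:
    """Parse a primer FASTA list into pairs, tags and unpaired records."""
    raw = list(SeqIO.parse(StringIO(text), "fasta"))
    if not raw:
        raise PrimerParseError("no FASTA records found in primer list")
    names_seen: set[str] = set()
    tag_f: PrimerRecord | None = None
    tag_r: PrimerRecord | None = None
    plain: list[tuple[str, str]] = []  # (name, sequence) in input order
    for rec in raw:
        name = rec.id
        if name in names_seen:
            raise PrimerParseError(f"duplicate record name {name!r}")
        names_seen.add(name)
        seq = _normalize(name, str(rec.seq))
        low = name.lower()
        if low == "tagf":
            if tag_f is not None:
                raise PrimerParseError("more than one tagF record")
            tag_f = PrimerRecord(name, seq, "tag-forward")
        elif low == "tagr":
            if tag_r is not None:
                raise PrimerParseError("more than one tagR record")
            tag_r = PrimerRecord(name, seq, "tag-reverse")
        else:
            plain.append((name, seq))

    # pair by full name except the final letter (F/R, case-insensitive)
    by_stem: dict[tuple[str, str], str] = {}
    for name, _ in plain:
        last = name[-1].upper()
        if last in "FR":
            by_stem[(name[:-1], last)] = name
    seqs = dict(plain)
    pairs: list[PrimerPair] = []
    unpaired: list[PrimerRecord] = []
    used: set[str] = set()
    index = 0
    for name, seq in plain:
        if name in used:
            continue
        last = name[-1].upper()
        if last == "F" and (name[:-1], "R") in by_stem:
            partner = by_stem[(name[:-1], "R")]
            pairs.append(
                PrimerPair(
                    amplicon_name=name[:-1],
                    forward=PrimerRecord(name, seq, "forward"),
                    reverse=PrimerRecord(partner, seqs[partner], "reverse"),
                    index=index,
                )
            )
            used.update((name, partner))
            index += 1
        elif last == "R" and (name[:-1], "F") in by_stem:
            partner = by_stem[(name[:-1], "F")]
            pairs.append(
                PrimerPair(
                    amplicon_name=name[:-1],
                    forward=PrimerRecord(partner, seqs[partner], "forward"),
                    reverse=PrimerRecord(name, seq, "reverse"),
                    index=index,
                )
            )
            used.update((name, partner))
            index += 1
        else:
            logger.warning(
                "primer %r has no F/R partner; analysed but not pooled", name
            )
            unpaired.append(PrimerRecord(name, seq, "unknown"))
            used.add(name)
    return PrimerSet(pairs=pairs, tag_forward=tag_f, tag_reverse=tag_r,
                     unpaired=unpaired)


class TagLengthError(ValueError):
    """A tagged primer exceeds the 128-base analysis limit."""


def apply_tags(pset: PrimerSet) -> PrimerSet:
    """Prepend tagF/tagR to every forward/reverse primer (5' end).

    The untagged sequence stays in ``PrimerRecord.sequence`` (the genome scan
    uses it); the tagged form is ``PrimerRecord.full_sequence``.
    """
    tf = pset.tag_forward.sequence if pset.tag_forward else ""
    tr = pset.tag_reverse.sequence if pset.tag_reverse else ""
    if not tf and not tr:
        return pset

    def tagged(rec: PrimerRecord, tag: str) -> PrimerRecord:
        if len(tag) + len(rec.sequence) > MAX_PRIMER_LEN:
            raise TagLengthError(
                f"primer {rec.name!r}: tagged length "
                f"{len(tag) + len(rec.sequence)} exceeds {MAX_PRIMER_LEN}"
            )
        return replace(rec, tag=tag)

    pairs = [
        PrimerPair(p.amplicon_name, tagged(p.forward, tf), tagged(p.reverse, tr),
                   p.index)
        for p in pset.pairs
    ]
    return PrimerSet(pairs=pairs, tag_forward=pset.tag_forward,
                     tag_reverse=pset.tag_reverse, unpaired=list(pset.unpaired))


def write_pool_fastas(
    assignment,
    pset: PrimerSet,
    out_dir: str | Path,
    single_file: bool = False,
    basename: str = "pool",
) -> list[Path]:
    """Write untagged primers grouped by pool.

    Multi-file mode writes ``pool1.fasta`` ... ``poolk.fasta``; single-file
    mode writes one ``pools.fasta`` with ``; pool N`` comment lines between
    groups.  ``assignment`` must cover every pair in ``pset``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_pool: dict[int, list[PrimerPair]] = {p: [] for p in range(1, assignment.k + 1)}
    for pair in pset.pairs:
        pool = assignment.pool_of.get(pair.index)
        if pool is None:
            raise ValueError(
                f"assignment missing pair {pair.amplicon_name!r} "
                f"(index {pair.index})"
            )
        by_pool[pool].append(pair)

    def fasta_records(pairs: list[PrimerPair]):
        for pair in pairs:
            for rec in (pair.forward, pair.reverse):
                yield SeqRecord(Seq(rec.sequence), id=rec.name, description="")

    written: list[Path] = []
    if single_file:
        path = out_dir / f"{basename}s.fasta"
        with open(path, "w") as fh:
            for pool in sorted(by_pool):
                fh.write(f"; pool {pool}\n")
                SeqIO.write(fasta_records(by_pool[pool]), fh, "fasta-2line")
        written.append(path)
    else:
        for pool in sorted(by_pool):
            path = out_dir / f"{basename}{pool}.fasta"
            with open(path, "w") as fh:
                SeqIO.write(fasta_records(by_pool[pool]), fh, "fasta-2line")
            written.append(path)
    return written
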