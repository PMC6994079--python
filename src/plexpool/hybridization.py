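"""Primer–primer interaction scoring.

Every unordered primer pair (including a primer against itself) is slid
through all antiparallel juxtapositions; only the extreme interaction is
kept, scored either as

* **match score** — bonded positions minus non-bonded positions strictly
  inside the bonded span, maximized over offsets; or
* **ΔG** (kcal/mol) — nearest-neighbour duplex free energy at the run
  temperature, minimized (most stable) over offsets.  Each maximal run of
  ≥2 consecutive bonds contributes its stack sum; a single internal mismatch
  flanked by bonds contributes its tabulated mismatch stacks; two or more
  consecutive mismatches break the duplex into independent segments.
  ΔG(T) = ΔH − (T + 273.15)·ΔS/1000 with an entropic salt correction of
  0.368·ln[Na+] cal/(mol·K) per stack.  Duplex initiation terms are omitted:
  interactions are compared relatively, so the constant offset is
  irrelevant to ranking and pooling.

Degenerate primers are scored worst-case: a column bonds if any base choice
on each side is complementary, and each stack takes the most stable
interpretation.  This lower-bounds the ΔG of every concrete variant, which
is the safe direction for pool separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from itertools import product

from . import nn_params
from .bitseq import (
    IUPAC_SETS,
    WATSON_CRICK,
    BondPattern,
    aligned_columns,
    bond_pattern,
    bond_pattern_degenerate,
    encode_degenerate,
    encode_exact,
    offsets,
)
from .primer_io import PrimerRecord, PrimerSet

KELVIN = 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Conditions for nearest-neighbour ΔG evaluation.

    temperature in °C; sodium (monovalent cation) in mol/L.
    """

    temperature: float = 37.0
    sodium: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 100.0:
            raise ValueError(f"temperature {self.temperature} outside [0, 100] °C")
        if self.sodium <= 0:
            raise ValueError("sodium concentration must be positive")

    @property
    def kelvin(self) -> float:
        return self.temperature + KELVIN

    def stack_dg(self, dh: float, ds: float) -> float:
        """ΔG of one stack after the entropic salt correction."""
        return dh - self.kelvin * (ds + 0.368 * math.log(self.sodium)) / 1000.0


@dataclass(frozen=True)
class InteractionResult:
    primer_a: str
    primer_b: str
    best_score: int = 0
    best_dg: float = 0.0
    best_offset_score: int = 0
    best_offset_dg: int = 0
    seq_a: str = ""
    seq_b: str = ""


@dataclass
class InteractionTable:
    """Symmetric lookup of the worst interaction per unordered primer pair."""

    mode: str  # "score" | "dG"
    results: dict[frozenset[str], InteractionResult] = field(default_factory=dict)

    def get(self, a: str, b: str) -> InteractionResult:
        return self.results[frozenset((a, b))]

    def put(self, result: InteractionResult) -> None:
        self.results[frozenset((result.primer_a, result.primer_b))] = result

    def __len__(self) -> int:
        return len(self.results)

    def value(self, a: str, b: str) -> float:
        r = self.get(a, b)
        return r.best_score if self.mode == "score" else r.best_dg


def _is_degenerate(seq: str) -> bool:
    return bool(set(seq) - set("ACGT"))


def _bond_patterns(seq1: str, seq2: str):
    """Yield (offset, BondPattern) over all juxtapositions, picking the
    exact or degenerate machinery as needed."""
    if _is_degenerate(seq1) or _is_degenerate(seq2):
        e1, e2 = encode_degenerate(seq1), encode_degenerate(seq2)
        for off in offsets(len(seq1), len(seq2)):
            yield off, bond_pattern_degenerate(e1, e2, off)
    else:
        e1, e2 = encode_exact(seq1), encode_exact(seq2)
        for off in offsets(len(seq1), len(seq2)):
            yield off, bond_pattern(e1, e2, off)


def _span_score(bp: BondPattern) -> int:
    """Bonds minus interior mismatches within the bonded span."""
    if bp.bonds == 0:
        return 0
    span = bp.bonds.bit_length() - (bp.bonds & -bp.bonds).bit_length() + 1
    return 2 * bp.count - span


def match_score(p1: str, p2: str, name1: str = "p1", name2: str = "p2") -> InteractionResult:
    """Best match score over all antiparallel offsets (ties: smallest offset)."""
    best, best_off = 0, 0
    for off, bp in _bond_patterns(p1, p2):
        s = _span_score(bp)
        if s > best:
            best, best_off = s, off
    return InteractionResult(name1, name2, best_score=best,
                             best_offset_score=best_off, seq_a=p1, seq_b=p2)


def _segments(flags: list[bool]) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of columns forming one stacked duplex:
    bonded columns plus single mismatches flanked by bonds."""
    segs: list[tuple[int, int]] = []
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        last_bond = i
        while j < n:
            if flags[j]:
                last_bond = j
                j += 1
            elif j + 1 < n and flags[j + 1]:  # single interior mismatch
                j += 1
            else:
                break
        segs.append((i, last_bond + 1))
        i = last_bond + 1
    return segs


def _step_params_exact(b1: str, c1: str, b2: str, c2: str) -> tuple[float, float]:
    """(ΔH, ΔS) for the step 5'-b1 c1-3' over 3'-b2 c2-5'."""
    return nn_params.lookup(b1 + c1, b2 + c2)


def _step_params_degenerate(
    s1a: str, s1b: str, s2a: str, s2b: str, bond_a: bool, bond_b: bool,
    temp: ThermoParams,
) -> tuple[float, float]:
    """Most stable (ΔH, ΔS) over base interpretations of a degenerate step.

    At bonded columns only complementary base choices are considered; at the
    (single) mismatch column any non-complementary choice is allowed.
    """
    best: tuple[float, float] | None = None
    best_g = math.inf
    for a1, a2 in product(IUPAC_SETS[s1a], IUPAC_SETS[s2a]):
        if ((a1, a2) in WATSON_CRICK) != bond_a:
            continue
        for b1, b2 in product(IUPAC_SETS[s1b], IUPAC_SETS[s2b]):
            if ((b1, b2) in WATSON_CRICK) != bond_b:
                continue
            try:
                dh, ds = nn_params.lookup(a1 + b1, a2 + b2)
            except nn_params.MissingStepError:
                continue
            g = temp.stack_dg(dh, ds)
            if g < best_g:
                best_g, best = g, (dh, ds)
    if best is None:
        raise nn_params.MissingStepError(
            f"no parameters for degenerate step {s1a}{s1b}/{s2a}{s2b}"
        )
    return best


def _offset_dg(seq1: str, seq2: str, offset: int, bp: BondPattern,
               params: ThermoParams, degenerate: bool) -> float:
    cols = list(aligned_columns(seq1, seq2, offset))
    if not cols:
        return 0.0
    flags = [bool(bp.bonds >> c & 1) for c, _, _, _ in cols]
    total = 0.0
    for start, end in _segments(flags):
        if sum(flags[start:end]) < 2:
            continue
        dh_sum = ds_sum = 0.0
        nstacks = 0
        for k in range(start, end - 1):
            _, _, b1, b2 = cols[k]
            _, _, c1, c2 = cols[k + 1]
            if degenerate:
                dh, ds = _step_params_degenerate(
                    b1, c1, b2, c2, flags[k], flags[k + 1], params)
            else:
                dh, ds = _step_params_exact(b1, c1, b2, c2)
            dh_sum += dh
            ds_sum += ds
            nstacks += 1
        total += dh_sum - params.kelvin * (
            ds_sum + 0.368 * nstacks * math.log(params.sodium)
        ) / 1000.0
    return total


def delta_g(p1: str, p2: str, params: ThermoParams,
            name1: str = "p1", name2: str = "p2") -> InteractionResult:
    """Most stable nearest-neighbour ΔG over all antiparallel offsets.

    Returns best_dg = 0.0 when no offset has two consecutive bonds (no
    stable interaction).  Ties broken by smallest offset.
    """
    degenerate = _is_degenerate(p1) or _is_degenerate(p2)
    best, best_off = 0.0, 0
    for off, bp in _bond_patterns(p1, p2):
        if bp.count < 2:
            continue
        g = _offset_dg(p1, p2, off, bp, params, degenerate)
        if g < best:
            best, best_off = g, off
    return InteractionResult(name1, name2, best_dg=best, best_offset_dg=best_off,
                             seq_a=p1, seq_b=p2)


def score_interaction(p1: str, p2: str, params: ThermoParams, mode: str,
                      name1: str = "p1", name2: str = "p2") -> InteractionResult:
    if mode == "score":
        return match_score(p1, p2, name1, name2)
    if mode == "dG":
        return delta_g(p1, p2, params, name1, name2)
    raise ValueError(f"unknown mode {mode!r} (expected 'score' or 'dG')")


def all_interactions(pset: PrimerSet, params: ThermoParams,
                     mode: str = "dG") -> InteractionTable:
    """Score every unordered primer pair, including self-interactions.

    Tagged forms are used when tags are present (the set should have gone
    through :func:`plexpool.primer_io.apply_tags` first).
    """
    records: list[PrimerRecord] = pset.records()
    table = InteractionTable(mode=mode)
    for i, a in enumerate(records):
        for b in records[i:]:
            table.put(score_interaction(a.full_sequence, b.full_sequence,
                                        params, mode, a.name, b.name))
    return table


def interaction_bin(result: InteractionResult, mode: str) -> int:
    """Histogram bin: the score itself, or int(−2×ΔG) (0.5 kcal/mol ranges)."""
    from .pooling import range_of

    return range_of(result.best_score if mode == "score" else result.best_dg, mode)


def summarize(table: InteractionTable) -> Counter[int]:
    """Counts of interactions per score / ΔG range; values sum to len(table)."""
    hist: Counter[int] = Counter()
    for result in table.results.values():
        hist[interaction_bin(result, table.mode)] += 1
    return hist


def bonding_diagram(result: InteractionResult, mode: str = "score") -> str:
    """Three-line ASCII rendering of the best juxtaposition.

    Line 1: primer A 5'->3'; line 2: bond marks; line 3: primer B 3'->5',
    shifted by the recorded offset.  Zero-bond interactions render as ''.
    """
    seq1, seq2 = result.seq_a, result.seq_b
    offset = result.best_offset_score if mode == "score" else result.best_offset_dg
    if not seq1 or not seq2:
        return ""
    if _is_degenerate(seq1) or _is_degenerate(seq2):
        bp = bond_pattern_degenerate(
            encode_degenerate(seq1), encode_degenerate(seq2), offset)
    else:
        bp = bond_pattern(encode_exact(seq1), encode_exact(seq2), offset)
    if bp.bonds == 0:
        return ""
    s1, s2 = (0, offset) if offset >= 0 else (-offset, 0)
    line1 = " " * s1 + seq1
    marks = "".join(
        "|" if bp.bonds >> c & 1 else " " for c in range(bp.width)
    ).rstrip()
    line2 = " " * 3 + marks
    line3 = " " * s2 + seq2[::-1]
    header = f"{result.primer_a} x {result.primer_b}: " + (
        f"score {result.best_score}" if mode == "score"
        else f"dG {result.best_dg:.2f} kcal/mol"
    )
    return "\n".join([header, "5'-" + line1 + "-3'", line2, "3'-" + line3 + "-5'"])


def render_report(table: InteractionTable, threshold: int,
                  diagrams: bool = True) -> str:
    """Histogram block plus worst-first bonding diagrams at/above threshold."""
    hist = summarize(table)
    lines = [f"Interactions by {'score' if table.mode == 'score' else 'dG range'}:"]
    for rng in sorted(hist, reverse=True):
        lines.append(f"  range {rng:>3}: {hist[rng]}")
    if diagrams:
        flagged = [
            r for r in table.results.values()
            if interaction_bin(r, table.mode) >= threshold
        ]
        if table.mode == "score":
            flagged.sort(key=lambda r: (-r.best_score, r.primer_a, r.primer_b))
        else:
            flagged.sort(key=lambda r: (r.best_dg, r.primer_a, r.primer_b))
        for r in flagged:
            d = bonding_diagram(r, table.mode)
            if d:
                lines.append("")
                lines.append(d)
    return "\n".join(lines)
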