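# Methods

## Scope and model

`plexpool` treats a multiplex PCR panel as three coupled problems: scoring
candidate primer–primer duplexes, locating the panel's amplicons on a
reference genome to find overlap conflicts, and partitioning primer pairs
into subpools that minimize the worst residual interaction. The sections
below record the exact model, the defaults and why, and the places where a
design choice was genuinely open.

## Duplex model

Two antiparallel primers are slid through every juxtaposition with at least
one aligned column (len₁ + len₂ − 1 offsets). A column *bonds* when the
bases are Watson–Crick complementary; no gaps, bulges, wobble pairs or
dangling ends are modelled. The two metrics per primer pair are:

* **Match score** = bonds − non-bonded columns strictly inside the bonded
  span, maximized over offsets. This definition rewards long complementary
  runs and penalizes interrupted ones; mismatches outside the bonded span
  are ignored (they do not stabilize or destabilize a duplex that never
  forms there). Equal scores at several offsets resolve to the smallest
  signed offset, making reports deterministic.
* **ΔG** = the minimum (most stable) over offsets of the nearest-neighbour
  free energy of that juxtaposition. Maximal stretches of columns
  containing no two consecutive mismatches, trimmed to their bonded ends,
  form independent duplex segments; a segment with ≥2 bonds contributes the
  sum of its dinucleotide stacks. Watson–Crick stacks use the unified
  oligonucleotide ΔH°/ΔS° set; a single internal mismatch flanked by bonds
  contributes the Allawi/Peyret single-mismatch stacks (`nn_params.py`,
  version tag `unified-1998+mismatch-allawi-peyret/1`; every entry is
  cross-checked in the test suite against the same published sets as
  independently transcribed in Biopython's melting-temperature module).
  ΔG(T) = ΔH° − T·ΔS°/1000 at the run temperature.

**Salt correction.** The entropic correction 0.368·ln[Na⁺] cal/(mol·K) is
applied per stack (each stack spans two phosphates, one per strand).
Defaults: 37 °C and 50 mM Na⁺; the worked examples and the acceptance
pipeline use 60 °C / 50 mM, typical annealing conditions for tagged panels.

**Initiation terms are omitted.** Pool partitioning ranks interactions
relative to one another; the duplex-initiation penalty is a near-constant
offset that would shift every ΔG without reordering them. Reported ΔG
values are therefore comparative, not absolute hybridization energies.

**Degenerate primers** are scored worst-case: a column bonds if *some*
base choice on each side is complementary (the four possibility planes
R_A/R_C/R_G/R_T make this a bitwise OR of four ANDs), and each stack takes
the most stable interpretation consistent with the column's bond status.
Because adjacent stacks may pick inconsistent bases, the result is a lower
bound on the ΔG of every concrete variant — the safe direction for pool
separation, verified as a property test. A primer pair with no two
consecutive bonds at any offset reports ΔG = 0 ("no stable interaction").

**Capacity.** Primers up to 128 bases after 5′-tag concatenation are
analysed. Planes live in arbitrary-precision integers, so the limit is a
contract (and an input-sanity guard), not a word-size constraint; results
are identical for any plane width.

## Genome scan

Primers are scanned untagged (tags are synthetic and never genomic). Every
concrete expansion of every primer, and its reverse complement, becomes an
index variant packed as a 2-bit window of its **last 32 bases** with a
validity mask; variants identical within the window are deduplicated.
*N* = min(shortest primer length, 32) defines fixed-length keys (the last
*N* bases of each variant) held sorted for binary search. Per chromosome,
a rolling 2-bit register yields the key ending at each position (vectorized
over the chromosome); key hits are verified against the full variant
window before a hit is recorded. Windows touching any non-ACGT base never
match; soft-masked lowercase matches as uppercase (primers legitimately
target masked repeats). This makes the scan exactly equivalent to
exhaustive string search over all variant windows — the test suite asserts
equality against that oracle — while touching each genome base once.

Primers longer than 32 bases are matched by their last 32 window bases
only and are listed in a warning; for such primers the reported site (and
the amplicon edge derived from it) reflects the matched window, so an
amplicon opened by a long primer's site is shortened by the unmatched
prefix length. Panels with >32-base tagged-free primers are rare; the
warning makes the approximation visible.

**Amplicons.** Hits are events on a positional sweep. A forward-role hit
on the + strand opens a positive-strand-first amplicon, closed by the same
pair's reverse-role hit on the − strand; the symmetric reverse-opens case
is negative-strand-first. An opener takes the *nearest* in-limit closer
(shortest product dominates a PCR); `max_len` is an inclusive bound on
end − start with both primers included. A pair may own several amplicons
at distinct loci (all participate in overlap checks); a pair with none is
reported unmatched with a warning, including the case where its two
primers map to different chromosomes. Coordinates are 0-based half-open
internally and rendered 1-based inclusive in reports.

**Overlaps.** Same-chromosome amplicons with intersecting intervals
(half-open; mere adjacency is not overlap) are enumerated by an active-set
sweep, checked against brute-force interval intersection in tests. Each
overlapping pair-of-pairs has its four cross-primer interaction entries
saturated (score 65535, or ΔG −32767.5 ⇒ range 65535) in a *copy* of the
interaction table, so the original values remain reportable and the
partitioner can never co-pool the two pairs.

**2bit support** implements the published UCSC layout directly (signature
0x1A412743, version 0, N-block and mask-block lists, T=0/C=1/A=2/G=3
packed four bases per byte, big bits first), reading either byte order and
writing little-endian. The fixture generator writes byte-identical twins
of its FASTA output, and scans of both are asserted equal.

## Pool partitioning

ΔG is mapped to half-kcal ranges, `range = int(−2·ΔG)` (truncation toward
zero, floored at 0); match scores are their own range. Range 0 — no
interaction — is never counted. An assignment is scored by the
lexicographic 4-tuple over the multiset of ranges of all co-pooled
cross-pair interactions: (d1 worst range, d2 count at d1, d3 count at
d1−1, d4 count at d1−2), counters saturating at 65535 (16-bit fields). A
pair's own F–R and self-dimer energies are pool-invariant and excluded
from the objective; they appear in the interaction report instead.

The search: uniform-random initial assignment (randomized round-robin when
a pool-size cap is set); repeat { apply the single-pair move with the
lexicographically best positive 4-tuple benefit — ties to the lowest pair
index, then lowest target pool — until a local optimum; if it beats the
saved best, save it; then perturb with 1..max(2, n/10) random moves, or
re-randomize entirely when the climb converged on a worse state than the
saved best }. The run stops after 200 cycles without improvement
(configurable `patience`), on an optional wall-clock limit, or on an
exhausted cycle budget, returning the saved best — which is monotone by
construction. A per-climb move cap (50·n) guards against pathological
benefit cycles: the per-pair move ranking does not formally guarantee
descent of the *global* lexicographic objective, though in practice it
does. On every ≤12-pair instance tested (5 seeds, 2–3 pools), the result
equals the exhaustive-search optimum.

`suggest_pool_count` mirrors practitioner heuristics: first-fit packing in
input order, placing each pair into the first pool where its worst
cross-interaction stays below range 14 (ΔG −7 kcal/mol, the customary
multiplex-design cutoff); saturated overlap entries can never pass, so
overlapping pairs force separate pools. The user's requested *k* always
overrides the suggestion.

## Synthetic data

The fixture generator emulates the package's input contract rather than
genome biology: primer lists with the F/R naming convention, optional
tagF/tagR, injected IUPAC wildcards; genomes of uniform ACGT background
with an optional N block, into which each requested amplicon's primer
sites are planted (forward at the start, reverse-complemented reverse at
the end, roles swapped for negative-strand-first); and block-structured
interaction tables with planted conflict cliques. Backgrounds containing
any *unplanned* occurrence of a primer window are re-drawn (bounded
retries), so planted ground truth — hits, amplicons, overlap sets — is
exact and scan tests need no tolerance. What this does **not** model:
repeat structure, GC skew, near-miss primer sites (the scanner is
exact-match by design, so mismatch tolerance is untested because it is a
non-feature), or realistic dimer-energy distributions; pooling results on
real panels will see a denser interaction spectrum than the planted
cliques, affecting runtime, not correctness of the objective.

Problem sizes in the shipped tests and acceptance script — 20 genomes of
40 kb, panels of 4–12 pairs, brute-force baselines at ≤12 pairs — were
chosen so the whole suite re-runs in seconds while still exercising every
code path (both strands, degeneracy, N blocks, multi-chromosome inputs,
overlap groups, size caps); the algorithms themselves are
dimension-independent, and the scan is vectorized per chromosome.

## Numerical and degenerate-input choices

* ΔG comparisons use exact float comparison for "best offset"; ties keep
  the smallest offset. Stack sums are short (≤127 terms), so accumulation
  error is far below the 0.5 kcal/mol range width.
* Empty primer lists, empty sequences, non-IUPAC characters, duplicate
  record names, >1 tagF/tagR, tagged length >128, degenerate expansion
  beyond 4096 variants per primer, k > number of pairs, and infeasible
  size caps all raise typed errors naming the offending record.
* An all-N chromosome, a chromosome shorter than *N*, and a genome with no
  primer sites each yield empty results, not errors.

## Known limitations

* No hairpin/secondary-structure model and no melting temperature — the
  tool ranks pairwise dimer potential only.
* ΔG values are comparative (no initiation terms, no divalent-cation
  correction); use a dedicated thermodynamics package for absolute values.
* Exact-match genome scanning: a primer site with even one mismatch is
  invisible, which is the desired semantics for overlap detection of a
  designed panel, not for off-target screening.
* The partitioner is a heuristic; optimality is verified only at
  brute-force-checkable sizes.
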