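# plexpool

Multiplex PCR primer pool partitioning.

Targeted sequencing panels routinely pool hundreds to thousands of PCR
primer pairs in one preamplification reaction before parallel low-plex PCR.
Two things go wrong in large pools: **primer dimers** (a primer
cross-hybridizes with another primer, or with itself, and the spurious
duplex competes with target amplification) and **overlapping amplicons**
(tiling designs place neighbouring amplicons so close that co-pooled pairs
generate short chimeric products). `plexpool` screens both problems and
then splits the primer pairs into a user-chosen number of subpools with
minimal residual interactions — for panel designers who have the primers
already and need to decide which primers may share a tube.

## What it computes

**1. Dimer screen.** Every inter-/intra-primer interaction (5' index tags
included) is slid through all antiparallel juxtapositions using bit-plane
arithmetic: a primer is packed into an A|T plane and a G|T plane so that
two aligned bases bond iff their A|T bits are equal and their G|T bits
differ,

```
bonds = XNOR(p1_AT, p2_AT) AND XOR(p1_GT, p2_GT) AND valid
```

with a four-plane variant (R_A, R_C, R_G, R_T possibility masks) for IUPAC
degenerate primers. Each interaction is scored either by base-match score
or, preferably, by nearest-neighbour free energy

```
ΔG(T) = ΔH° − T·ΔS°/1000          (kcal/mol, T in kelvin)
```

summed over dinucleotide stacks (unified Watson–Crick parameters plus the
Allawi/Peyret internal single-mismatch sets, with an entropic salt
correction of 0.368·ln[Na+] cal/(mol·K) per stack). Only the most stable
offset is kept per primer pair.

**2. Genome scan.** All primers (every concrete expansion of degenerate
primers, plus reverse complements) are packed into 2-bit windows of their
last ≤32 bases. The genome (.2bit or FASTA) is streamed once — no index —
and at every position the last *N* bases (*N* = shortest primer length)
are binary-searched among the variant keys; full windows are verified only
on key hits. Convergent forward/reverse sites within the maximum amplicon
length become amplicons; overlapping amplicons are reported and their
pairs' mutual interaction entries are saturated so the partitioner must
separate them.

**3. Pool partitioning.** An assignment of pairs to *k* pools is scored by
the lexicographic 4-tuple (worst interaction range present; count at that
range; count one below; count two below), where ΔG maps to half-kcal
ranges via `range = int(−2·ΔG)`. Exhaustive search is hopeless (100 pairs
in 2 pools is already 2¹⁰⁰ ≈ 10³⁰·¹ assignments), so the partitioner hill
climbs from a random assignment — always taking the best-ranked
beneficial single-pair move — then escapes local optima with random bad
moves or full re-randomization, keeping the best state ever seen.

## Worked example

```python
from plexpool import (parse_primer_fasta, apply_tags, all_interactions,
                      ThermoParams, PairMatrix, partition, suggest_pool_count)
from plexpool.hybridization import render_report

text = """>tagF
Acactgacgacatggttctaca
>tagR
tacggtagcagagacttggtct
>ARID1A_ex1-F
CGCCGTCTTCCACCAACAA
>ARID1A_ex1-R
GGTAGGCGCTGCGGTT
>CCND3_ex2_1-F
CtY c ag acc cagc agtga
>CCND3_ex2_1-R
GATG gTCAGGGGCGTGGT
"""
pset = apply_tags(parse_primer_fasta(text))
print(pset.summary())
table = all_interactions(pset, ThermoParams(temperature=60.0, sodium=0.05),
                         mode="dG")
print(render_report(table, threshold=14, diagrams=False))
matrix = PairMatrix.from_table(table, pset)
print("suggested pools:", suggest_pool_count(matrix))
res = partition(matrix, 2, seed=0)
print("assignment:", res.assignment.pool_of, "score:", res.score.as_tuple())
```

prints

```
{'n_primers': 4, 'n_pairs': 2, 'min_length': 16, 'max_length': 19,
 'max_tag_length': 22, 'max_tagged_length': 41}
Interactions by dG range:
  range  10: 1
  range   8: 3
  range   7: 3
  range   6: 2
  range   5: 1
suggested pools: 1
assignment: {0: 1, 1: 2} score: (0, 0, 0, 0)
```

Pairing happened by name (`...-F`/`...-R`; last letter only), mixed case
and embedded spaces were normalized, and the 22-base tags were prepended
before scoring. The worst of the ten tagged interactions falls in range 10
(ΔG ≈ −5 kcal/mol at 60 °C, 50 mM Na⁺) — below the −7 kcal/mol alarm
threshold (range 14), so a single pool would already be acceptable
(`suggested pools: 1`). Forced to 2 pools, the final score `(0, 0, 0, 0)`
says no cross-pair interaction range above zero remains inside any pool.

The same pipeline, genome scan included, from a shell:

```bash
plexpool --primers primers.fasta --genome hg38.2bit --max-amplicon-len 400 \
         --mode dg --temp 60 --na 0.05 --pools 3 --seed 1 --out-dir out/
```

which writes `out/interactions.txt`, `out/overlaps.txt`,
`out/amplicons.bed` and one FASTA per subpool.

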