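"""Index-free genome scan, amplicon reconstruction and overlap detection."""

import random

import pytest

from plexpool.bitseq import reverse_complement
from plexpool.fixtures import (
    FixtureSpec,
    PlantedAmplicon,
    make_genome,
    make_primer_set,
)
from plexpool.genomescan import (
    Amplicon,
    GenomeFormatError,
    binary_search_key,
    build_variant_index,
    detect_overlaps,
    find_amplicons,
    overlap_constraints,
    read_genome,
    scan_chromosome,
    scan_genome,
)
from plexpool.hybridization import ThermoParams, all_interactions
from plexpool.pooling import PairMatrix, RANGE_SATURATION, partition, range_of
from plexpool.primer_io import parse_primer_fasta


def string_search_hits(sequences: dict[str, str], pset) -> set[tuple]:
    """Exact-string-search oracle: every occurrence of every concrete
    variant of every primer window, both strands (last 32 bases only)."""
    from plexpool.bitseq import expand_degenerate

    found = set()
    primers = []
    for p in pset.pairs:
        primers.append((p.forward.name, p.forward.sequence))
        primers.append((p.reverse.name, p.reverse.sequence))
    for rec in pset.unpaired:
        primers.append((rec.name, rec.sequence))
    for chrom, seq in sequences.items():
        seq = seq.upper()
        for name, primer in primers:
            for concrete in expand_degenerate(primer):
                for strand, oriented in (("+", concrete),
                                         ("-", reverse_complement(concrete))):
                    probe = oriented[-32:]
                    at = seq.find(probe)
                    while at != -1:
                        window = seq[at:at + len(probe)]
                        if set(window) <= set("ACGT"):
                            found.add((name, chrom, at, at + len(probe), strand))
                        at = seq.find(probe, at + 1)
    return found


def as_tuples(hits) -> set[tuple]:
    return {(h.primer_name, h.chromosome, h.start, h.end, h.strand)
            for h in hits}


def test_variant_index_n_is_shortest_primer():
    pset = parse_primer_fasta(
        ">a-F\n" + "ACGTACGTACGTACGTAC\n"      # 18
        ">a-R\n" + "GGTTCCAACCGGTTCCAACCGG\n"  # 22
    )
    assert build_variant_index(pset).n == 18


def test_variant_index_degenerate_expansion_count():
    pset = parse_primer_fasta(">a-F\nNAAAAAAAAAAAAAAAAA\n>a-R\nCCGGCCGGCCGGCCGGCC\n")
    index = build_variant_index(pset)
    a_variants = [v for v in index.variants if v.primer_name == "a-F"]
    assert len(a_variants) == 4 * 2  # 4 expansions x 2 strands


def test_long_primer_flagged_and_matched_by_last_32_bases(rng):
    primer = "".join(rng.choice("ACGT") for _ in range(40))
    other = "".join(rng.choice("ACGT") for _ in range(20))
    pset = parse_primer_fasta(f">a-F\n{primer}\n>a-R\n{other}\n")
    index = build_variant_index(pset)
    assert index.long_primers == ["a-F"]
    # genome contains only the last 32 bases, preceded by a different prefix
    genome = "T" * 50 + primer[-32:] + "G" * 50
    hits = [h for h in scan_chromosome("chr1", genome, index)
            if h.primer_name == "a-F"]
    assert len(hits) == 1
    assert hits[0].start == 50 and hits[0].end == 82 and hits[0].strand == "+"


def test_planted_primer_found_at_exact_coordinates(rng):
    primer = "GATTACAGATTACAGATT"
    other = "CCGGTTAACCGGTTAACC"
    pset = parse_primer_fasta(f">a-F\n{primer}\n>a-R\n{other}\n")
    background = "".join(rng.choice("AC") for _ in range(300))
    genome = (background[:100] + primer + background[118:150]
              + reverse_complement(primer) + background[168:])
    hits = [h for h in scan_chromosome("chr1", genome, build_variant_index(pset))
            if h.primer_name == "a-F"]
    assert len(hits) == 2
    plus, minus = hits
    assert (plus.strand, plus.start, plus.pos3) == ("+", 100, 117)
    assert (minus.strand, minus.start, minus.pos3) == ("-", 150, 150)


def test_all_n_genome_has_no_hits():
    pset = parse_primer_fasta(">a-F\nACGTACGTACGTACGTAC\n>a-R\nGGTTCCAACCGGTTCCAA\n")
    assert scan_chromosome("chr1", "N" * 500, build_variant_index(pset)) == []


def test_scan_matches_string_search_oracle_on_synthetic_genomes():
    """Completeness and soundness, both strands, with degenerate primers."""
    for seed in range(5):
        spec = FixtureSpec(seed=seed, n_pairs=4, genome_len=8000,
                           n_degenerate=2,
                           n_block=(3900, 60))
        pset = make_primer_set(spec)
        genome = make_genome(spec, pset)
        hits = scan_genome(genome.sequences.items(),
                           build_variant_index(pset))
        assert as_tuples(hits) == string_search_hits(genome.sequences, pset)
        assert as_tuples(hits) == as_tuples(genome.expected_hits)


def test_fasta_and_2bit_scans_identical(tmp_path):
    spec = FixtureSpec(seed=11, n_pairs=3, genome_len=6000,
                       chromosomes=("chr1", "chr2"), n_block=(100, 40))
    spec.planted = [
        PlantedAmplicon(0, "chr1", 500, 200),
        PlantedAmplicon(1, "chr2", 800, 250),
        PlantedAmplicon(2, "chr2", 3000, 180),
    ]
    pset = make_primer_set(spec)
    genome = make_genome(spec, pset)
    fa = genome.write_fasta(tmp_path / "g.fa")
    tb = genome.write_2bit(tmp_path / "g.2bit")
    assert dict(read_genome(fa)) == dict(read_genome(tb))
    index = build_variant_index(pset)
    assert (scan_genome(read_genome(fa), index)
            == scan_genome(read_genome(tb), index))


def test_read_genome_errors(tmp_path):
    missing = tmp_path / "nope.fa"
    with pytest.raises(GenomeFormatError):
        list(read_genome(missing))
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(GenomeFormatError):
        list(read_genome(empty))
    junk = tmp_path / "junk.bin"
    junk.write_bytes(b"\x00" * 64)
    with pytest.raises(GenomeFormatError):
        list(read_genome(junk))


def test_soft_masked_bases_match():
    primer = "GATTACAGATTACAGATT"
    pset = parse_primer_fasta(f">a-F\n{primer}\n>a-R\nCCGGTTAACCGGTTAACC\n")
    genome = "t" * 30 + primer.lower() + "g" * 30
    hits = scan_chromosome("chr1", genome, build_variant_index(pset))
    assert any(h.primer_name == "a-F" and h.start == 30 for h in hits)


def test_binary_search_key_membership():
    keys = [3, 17, 99, 256]
    assert binary_search_key(keys, 99)
    assert not binary_search_key(keys, 98)
    assert not binary_search_key([], 1)


def test_find_amplicons_within_limit():
    spec = FixtureSpec(seed=2, n_pairs=2, genome_len=4000)
    spec.planted = [
        PlantedAmplicon(0, "chr1", 100, 100),
        PlantedAmplicon(1, "chr1", 1000, 300,
                        orientation="negative-strand-first"),
    ]
    pset = make_primer_set(spec)
    genome = make_genome(spec, pset)
    hits = scan_genome(genome.sequences.items(), build_variant_index(pset))
    amplicons = find_amplicons(hits, max_len=300)
    assert amplicons == genome.expected_amplicons
    assert {a.orientation for a in amplicons} == {
        "positive-strand-first", "negative-strand-first"}


def test_amplicon_longer_than_limit_reported_unmatched():
    spec = FixtureSpec(seed=2, n_pairs=2, genome_len=4000)
    spec.planted = [
        PlantedAmplicon(0, "chr1", 100, 100),
        PlantedAmplicon(1, "chr1", 1000, 300),
    ]
    pset = make_primer_set(spec)
    genome = make_genome(spec, pset)
    hits = scan_genome(genome.sequences.items(), build_variant_index(pset))
    amplicons = find_amplicons(hits, max_len=150)
    assert [a.pair_id for a in amplicons] == [0]
    report = detect_overlaps(amplicons, all_pair_ids=[0, 1])
    assert report.unmatched_pairs == [1]


def test_single_primer_hit_forms_no_amplicon():
    spec = FixtureSpec(seed=4, n_pairs=1, genome_len=2000)
    spec.planted = [PlantedAmplicon(0, "chr1", 100, 120)]
    pset = make_primer_set(spec)
    genome = make_genome(spec, pset)
    hits = scan_genome(genome.sequences.items(), build_variant_index(pset))
    only_forward = [h for h in hits if h.role == "forward"]
    assert find_amplicons(only_forward, max_len=500) == []


def brute_force_overlaps(amplicons):
    out = set()
    for i, a in enumerate(amplicons):
        for b in amplicons[i + 1:]:
            if (a.chromosome == b.chromosome
                    and max(a.start, b.start) < min(a.end, b.end)):
                out.add(frozenset([(a.pair_id, a.start, a.end),
                                   (b.pair_id, b.start, b.end)]))
    return out


@pytest.mark.parametrize("seed", range(3))
def test_overlap_sweep_equals_brute_force(seed):
    rng = random.Random(seed)
    amplicons = []
    for i in range(50):
        start = rng.randrange(0, 5000)
        amplicons.append(Amplicon(i, rng.choice(["chr1", "chr2"]),
                                  start, start + rng.randrange(50, 400),
                                  "positive-strand-first"))
    report = detect_overlaps(sorted(amplicons,
                                    key=lambda a: (a.chromosome, a.start)))
    got = {frozenset([(a.pair_id, a.start, a.end),
                      (b.pair_id, b.start, b.end)])
           for a, b, _ in report.overlaps}
    assert got == brute_force_overlaps(amplicons)


def test_adjacent_amplicons_do_not_overlap():
    amps = [Amplicon(0, "chr1", 100, 200, "positive-strand-first"),
            Amplicon(1, "chr1", 200, 300, "positive-strand-first")]
    assert detect_overlaps(amps).overlaps == []


def test_overlapping_intervals_shared_region():
    amps = [Amplicon(0, "chr1", 100, 200, "positive-strand-first"),
            Amplicon(1, "chr1", 150, 261, "positive-strand-first")]
    ((a, b, shared),) = detect_overlaps(amps).overlaps
    assert shared == (150, 200)


def test_overlap_constraints_saturate_cross_entries():
    spec = FixtureSpec(seed=6, n_pairs=3, genome_len=5000)
    pset = make_primer_set(spec)
    params = ThermoParams(temperature=37.0, sodium=0.05)
    table = all_interactions(pset, params, mode="dG")
    amps = [Amplicon(0, "chr1", 100, 300, "positive-strand-first"),
            Amplicon(1, "chr1", 250, 500, "positive-strand-first"),
            Amplicon(2, "chr1", 1000, 1200, "positive-strand-first")]
    report = detect_overlaps(amps)
    constrained = overlap_constraints(report, table, pset)
    p0, p1, p2 = pset.pairs
    for x in (p0.forward, p0.reverse):
        for y in (p1.forward, p1.reverse):
            assert range_of(constrained.value(x.name, y.name),
                            "dG") == RANGE_SATURATION
            # original values recoverable from the input table
            assert table.value(x.name, y.name) > -1000
    assert constrained.value(p0.forward.name, p2.forward.name) == table.value(
        p0.forward.name, p2.forward.name)


def test_overlap_constraints_empty_report_is_identity():
    spec = FixtureSpec(seed=6, n_pairs=2, genome_len=4000)
    pset = make_primer_set(spec)
    table = all_interactions(pset, ThermoParams(), mode="dG")
    out = overlap_constraints(detect_overlaps([]), table, pset)
    assert out.results == table.results


def test_overlapping_pairs_never_co_pooled_end_to_end():
    spec = FixtureSpec(seed=9, n_pairs=4, genome_len=6000)
    spec.planted = [
        PlantedAmplicon(0, "chr1", 200, 150, overlap_group=1),
        PlantedAmplicon(1, "chr1", 300, 160, overlap_group=1),
        PlantedAmplicon(2, "chr1", 2000, 150),
        PlantedAmplicon(3, "chr1", 4000, 150),
    ]
    pset = make_primer_set(spec)
    genome = make_genome(spec, pset)
    hits = scan_genome(genome.sequences.items(), build_variant_index(pset))
    amplicons = find_amplicons(hits, max_len=400)
    report = detect_overlaps(amplicons, all_pair_ids=[0, 1, 2, 3])
    assert report.overlapping_pair_ids() == {(0, 1)}
    table = all_interactions(pset, ThermoParams(), mode="dG")
    constrained = overlap_constraints(report, table, pset)
    matrix = PairMatrix.from_table(constrained, pset)
    for seed in range(3):
        result = partition(matrix, 2, seed=seed, patience=10)
        assert (result.assignment.pool_of[0]
                != result.assignment.pool_of[1])
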