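import random

import pytest

from plexpool.bitseq import WATSON_CRICK, aligned_columns, offsets


def naive_bond_count(seq1: str, seq2: str, offset: int) -> int:
    """Per-base reference: count complementary aligned columns with p2
    antiparallel."""
    return sum(
        1 for _, _, b1, b2 in aligned_columns(seq1, seq2, offset)
        if (b1, b2) in WATSON_CRICK
    )


def naive_best_match_score(seq1: str, seq2: str) -> tuple[int, int]:
    """Exhaustive per-offset per-base scorer: bonds minus interior
    mismatches within the bonded span; ties to the smallest offset."""
    best, best_off = 0, 0
    for off in offsets(len(seq1), len(seq2)):
        cols = [(b1, b2) in WATSON_CRICK
                for _, _, b1, b2 in aligned_columns(seq1, seq2, off)]
        bonded = [i for i, b in enumerate(cols) if b]
        if not bonded:
            continue
        span = bonded[-1] - bonded[0] + 1
        score = 2 * len(bonded) - span
        if score > best:
            best, best_off = score, off
    return best, best_off


def random_seq(rng: random.Random, min_len: int = 1, max_len: int = 20,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet)
                   for _ in range(rng.randint(min_len, max_len)))


@pytest.fixture
def rng():
    return random.Random(20260920)
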