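"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mircall.seqio import revcomp

# ---------------------------------------------------------------------------
# Independent oracles.  These deliberately use the dumbest possible
# algorithms (full scans, exhaustive recursion) so they share no code path
# with the implementation they check.

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum nested-pair count by exhaustive recursion (no memoisation)."""
    seq = sequence.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def naive_scan(genome: dict[str, str], read: str) -> set[tuple[str, int, int, str]]:
    """All exact occurrences of a read via sliding full scans, both strands."""
    hits = set()
    rc = revcomp(read)
    for chrom, seq in genome.items():
        start = seq.find(read)
        while start != -1:
            hits.add((chrom, start, start + len(read), "+"))
            start = seq.find(read, start + 1)
        start = seq.find(rc)
        while start != -1:
            hits.add((chrom, start, start + len(read), "-"))
            start = seq.find(rc, start + 1)
    return hits


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def tiny_genome_fasta(tmp_path):
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\nACGTACGTACGTACGTACGTACGTACGTACGT\n>chr2\nTTTTAAAACCCCGGGG\n")
    return path
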