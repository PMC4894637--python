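"""Exact placement of collapsed reads on a genome.

Reads are placed by exact, full-length, ungapped matching on both strands.
A k-mer index (default k = 12) seeds candidate positions which are then
verified over the full read length.  Every genomic occurrence is reported:
multi-mapping is preserved, and each placement carries the total number of
occurrences of its read (``multiplicity``) so that repeat-derived candidates
can be flagged downstream.  Multi-mapped reads are counted at full weight at
every placement; no fractional allocation is performed.

``total_aligned`` — the library-size denominator for reads-per-million —
counts each aligned read's collapsed count exactly once, regardless of how
many places it maps.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .seqio import GenomeSequence, Strain, StrainLibrary, revcomp


@dataclass(frozen=True)
class ReadPlacement:
    """One exact occurrence of a read on the genome.

    Coordinates are 0-based, half-open.  For strand '-', the read equals the
    reverse complement of the genomic slice.  ``count`` is the collapsed
    multiplicity of the read within its library; ``multiplicity`` the number
    of genomic occurrences of the read sequence (both strands, whole genome).
    """

    read_sequence: str
    chrom_id: str
    start: int
    end: int
    strand: str
    multiplicity: int
    count: int = 1


class GenomeIndex:
    """k-mer seed index over a genome, with full-length verification."""

    def __init__(self, genome: Mapping[str, GenomeSequence], k: int = 12):
        if not genome:
            raise ValueError("genome is empty")
        if k < 1:
            raise ValueError("k must be positive")
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom_id in sorted(genome):
            seq = genome[chrom_id].sequence
            for pos in range(len(seq) - k + 1):
                index[seq[pos:pos + k]].append((chrom_id, pos))
        self._index = dict(index)

    def occurrences(self, read: str) -> list[tuple[str, int]]:
        """All exact forward-strand occurrences of ``read`` in the genome."""
        k = self.k
        if len(read) < k:
            raise ValueError(f"read shorter than seed length k={k}: {read!r}")
        hits = []
        for chrom_id, pos in self._index.get(read[:k], ()):
            if self.genome[chrom_id].sequence[pos:pos + len(read)] == read:
                hits.append((chrom_id, pos))
        return hits


@dataclass
class PlacementSet:
    """Per-strain placements plus per-strain aligned-read totals."""

    placements: dict[Strain, list[ReadPlacement]]
    total_aligned: dict[Strain, int]
    _index: dict | None = field(default=None, repr=False, compare=False)

    def strand_index(self):
        """Lazily built per-strain, per-(chrom, strand) start-sorted index."""
        if self._index is None:
            idx: dict[Strain, dict[tuple[str, str], tuple[list[int], list[ReadPlacement]]]] = {}
            for strain, places in self.placements.items():
                groups: dict[tuple[str, str], list[ReadPlacement]] = defaultdict(list)
                for p in places:
                    groups[(p.chrom_id, p.strand)].append(p)
                idx[strain] = {
                    key: ([p.start for p in group], group)
                    for key, group in (
                        (key, sorted(group, key=lambda p: (p.start, p.end, p.read_sequence)))
                        for key, group in groups.items()
                    )
                }
            self._index = idx
        return self._index

    def contained(self, strain: Strain, chrom: str, strand: str, lo: int, hi: int):
        """Placements of ``strain`` fully contained in [lo, hi)."""
        entry = self.strand_index().get(strain, {}).get((chrom, strand))
        if entry is None:
            return
        starts, group = entry
        i = bisect_left(starts, lo)
        while i < len(group) and group[i].start < hi:
            if group[i].end <= hi:
                yield group[i]
            i += 1


def map_reads(
    libraries: Mapping[Strain, StrainLibrary] | StrainLibrary,
    genome: Mapping[str, GenomeSequence],
    k: int = 12,
) -> PlacementSet:
    """Place every read of every library on the genome, both strands.

    A read with zero occurrences contributes nothing.  Placement lists are
    sorted by (chrom, start, end, strand, sequence) so the output does not
    depend on read input order.  Each library's ``total_aligned`` attribute
    is set as a side effect.
    """
    if isinstance(libraries, StrainLibrary):
        libraries = {libraries.strain: libraries}
    shortest = min(
        (r.length for lib in libraries.values() for r in lib.reads),
        default=k,
    )
    if k > shortest:
        raise ValueError(
            f"seed length k={k} exceeds shortest read length {shortest}"
        )
    index = GenomeIndex(genome, k=k)

    # Resolve each unique sequence once across all libraries.
    unique: set[str] = set()
    for lib in libraries.values():
        unique.update(r.sequence for r in lib.reads)
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for seq in sorted(unique):
        fwd = [(c, p, "+") for c, p in index.occurrences(seq)]
        rev = [(c, p, "-") for c, p in index.occurrences(revcomp(seq))]
        hits[seq] = fwd + rev

    placements: dict[Strain, list[ReadPlacement]] = {}
    totals: dict[Strain, int] = {}
    for strain, lib in libraries.items():
        out: list[ReadPlacement] = []
        aligned = 0
        for read in lib.reads:
            occ = hits[read.sequence]
            if not occ:
                continue
            aligned += read.count
            mult = len(occ)
            for chrom, pos, strand in occ:
                out.append(ReadPlacement(
                    read_sequence=read.sequence,
                    chrom_id=chrom,
                    start=pos,
                    end=pos + read.length,
                    strand=strand,
                    multiplicity=mult,
                    count=read.count,
                ))
        out.sort(key=lambda p: (p.chrom_id, p.start, p.end, p.strand, p.read_sequence))
        placements[strain] = out
        totals[strain] = aligned
        lib.total_aligned = aligned
    return PlacementSet(placements=placements, total_aligned=totals)


def write_bed(placements: list[ReadPlacement], path: str | Path) -> None:
    """Export placements as BED6 (0-based half-open; score = count)."""
    with open(path, "w") as fh:
        for p in placements:
            fh.write(
                f"{p.chrom_id}\t{p.start}\t{p.end}\t{p.read_sequence}\t"
                f"{p.count}\t{p.strand}\n"
            )
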