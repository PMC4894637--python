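"""Input/output for genomes, small-RNA libraries and external evidence.

Sequences are stored internally in the DNA alphabet (A, C, G, T); mature
miRNA sequences are reported to the user in the RNA alphabet, following the
typography of the field.  Reads are collapsed to unique sequences with
summed multiplicities at load time, after a permissive length prefilter
([15, 40] nt by default).  The prefilter is deliberately wider than the
20-24 nt mature-length criterion: background and degradation reads must
survive loading so that the classifier, not the parser, applies that
criterion.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

log = logging.getLogger(__name__)

_DNA = set("ACGT")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_TO_RNA = str.maketrans("T", "U")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Strain(enum.Enum):
    """The three genetic backgrounds of the discovery contrast.

    WT is the AX2 wild type; PROC_MUTANT the microprocessor mutant (rbdB-)
    in which miRNAs are lost; SUPP_MUTANT the Argonaute knockout (agnA-) in
    which miRNA levels rise several-fold.
    """

    WT = "wt"
    PROC_MUTANT = "proc_mutant"
    SUPP_MUTANT = "supp_mutant"


def dna(seq: str) -> str:
    """Normalize a sequence to the internal uppercase DNA alphabet."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence in the RNA alphabet."""
    return seq.upper().translate(_DNA_TO_RNA)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome over the {A,C,G,T} alphabet."""

    chrom_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed read: one unique sequence with its multiplicity."""

    sequence: str
    count: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        return rna(self.sequence)


@dataclass
class StrainLibrary:
    """All collapsed reads of one strain's small-RNA library."""

    strain: Strain
    reads: list[SmallRNARead]
    total_aligned: Optional[int] = None
    n_input: int = 0
    n_dropped_length: int = 0
    n_dropped_alphabet: int = 0

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a genome FASTA into a mapping of chromosome id -> sequence.

    Sequences are uppercased and U is normalized to T.  Records are keyed by
    the first whitespace-delimited token of the header.  Any character outside
    {A,C,G,T} after normalization (including IUPAC ambiguity codes) is an
    error, as are duplicate chromosome ids and an empty file.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        chrom_id = record.id
        if chrom_id in genome:
            raise ValueError(f"duplicate chromosome id {chrom_id!r} in {path}")
        seq = dna(str(record.seq))
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"chromosome {chrom_id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        genome[chrom_id] = GenomeSequence(chrom_id, seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return "empty"
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: not FASTA or FASTQ (first character {first!r})")


def load_reads(
    path: str | Path,
    strain: Strain,
    min_len: int = 15,
    max_len: int = 40,
) -> StrainLibrary:
    """Load a small-RNA library (FASTA or FASTQ, auto-detected).

    Identical sequences are collapsed into one :class:`SmallRNARead` with a
    summed count.  Reads outside ``[min_len, max_len]`` and reads containing
    characters other than A/C/G/T/U (e.g. N calls, which the exact mapper
    could not place) are dropped; drop counts are logged and recorded on the
    returned library.  Quality strings are ignored.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    counts: Counter[str] = Counter()
    n_input = n_len = n_alpha = 0
    if fmt != "empty":
        for record in SeqIO.parse(str(path), fmt):
            n_input += 1
            seq = dna(str(record.seq))
            if set(seq) - _DNA:
                n_alpha += 1
                continue
            if not (min_len <= len(seq) <= max_len):
                n_len += 1
                continue
            counts[seq] += 1
    if n_len or n_alpha:
        log.info(
            "%s: dropped %d reads outside [%d,%d] nt and %d with non-ACGT "
            "characters (of %d)",
            path.name, n_len, min_len, max_len, n_alpha, n_input,
        )
    reads = [SmallRNARead(seq, c) for seq, c in counts.items()]
    return StrainLibrary(
        strain=strain,
        reads=reads,
        n_input=n_input,
        n_dropped_length=n_len,
        n_dropped_alphabet=n_alpha,
    )


def write_reads_fasta(library: StrainLibrary, path: str | Path) -> None:
    """Write a collapsed library as FASTA; counts are encoded in headers."""
    with open(path, "w") as fh:
        for i, read in enumerate(library.reads):
            fh.write(f">read_{i}_x{read.count}\n{read.sequence}\n")


def load_collapsed_fasta(path: str | Path, strain: Strain, **kwargs) -> StrainLibrary:
    """Re-load a FASTA written by :func:`write_reads_fasta`, restoring counts."""
    path = Path(path)
    counts: Counter[str] = Counter()
    n_input = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_input += 1
        mult = 1
        if "_x" in record.id:
            try:
                mult = int(record.id.rsplit("_x", 1)[1])
            except ValueError:
                mult = 1
        counts[dna(str(record.seq))] += mult
    reads = [SmallRNARead(seq, c) for seq, c in counts.items()]
    return StrainLibrary(strain=strain, reads=reads, n_input=n_input)


# ---------------------------------------------------------------------------
# External evidence (Northern blot detectability), an experimental input that
# is never computed.


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-locus experimental evidence.

    ``northern`` is tri-state: True / False / None (unknown).  The override
    flags allow blot evidence to stand in for the two expression criteria
    when sequencing depth is insufficient, mirroring how non-canonical loci
    can be credited "based on NB".
    """

    northern: Optional[bool] = None
    override_c2: bool = False
    override_c3: bool = False


@dataclass
class EvidenceTable:
    records: dict[str, EvidenceRecord] = field(default_factory=dict)

    def get(self, locus_id: str) -> Optional[EvidenceRecord]:
        return self.records.get(locus_id)

    def match_region(
        self, chrom: str, start: int, end: int, strand: str,
        min_overlap: float = 0.5,
    ) -> Optional[EvidenceRecord]:
        """Find evidence keyed by a region id overlapping a genomic window.

        Region ids have the form ``chrom:start-end(strand)`` (0-based,
        half-open).  The best reciprocal overlap >= ``min_overlap`` wins.
        """
        best, best_frac = None, 0.0
        for key, rec in self.records.items():
            parsed = parse_region_id(key)
            if parsed is None:
                continue
            c, s, e, st = parsed
            if c != chrom or st != strand:
                continue
            ov = min(end, e) - max(start, s)
            if ov <= 0:
                continue
            frac = min(ov / (end - start), ov / (e - s))
            if frac >= min_overlap and frac > best_frac:
                best, best_frac = rec, frac
        return best


def region_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}({strand})"


def parse_region_id(key: str) -> Optional[tuple[str, int, int, str]]:
    try:
        rest, strand = key.rsplit("(", 1)
        strand = strand.rstrip(")")
        chrom, span = rest.rsplit(":", 1)
        start, end = span.split("-")
        return chrom, int(start), int(end), strand
    except ValueError:
        return None


_TRI = {"1": True, "0": False, "NA": None, "": None}


def load_evidence(path: str | Path) -> EvidenceTable:
    """Load an evidence TSV.

    Header: ``locus_id<TAB>northern_detectable`` with optional
    ``override_c2`` / ``override_c3`` columns; values are 1/0/NA.
    """
    path = Path(path)
    table = EvidenceTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        if "locus_id" not in idx or "northern_detectable" not in idx:
            raise ValueError(f"{path}: expected locus_id and northern_detectable columns")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            locus_id = fields[idx["locus_id"]]
            if locus_id in table.records:
                raise ValueError(f"{path}: duplicate locus_id {locus_id!r}")

            def tri(col: str):
                if col in idx and idx[col] < len(fields):
                    return _TRI[fields[idx[col]]]
                return None

            table.records[locus_id] = EvidenceRecord(
                northern=tri("northern_detectable"),
                override_c2=bool(tri("override_c2")),
                override_c3=bool(tri("override_c3")),
            )
    return table


def write_evidence(table: EvidenceTable, path: str | Path) -> None:
    def fmt(v):
        return "NA" if v is None else str(int(v))

    with open(path, "w") as fh:
        fh.write("locus_id\tnorthern_detectable\toverride_c2\toverride_c3\n")
        for locus_id, rec in table.records.items():
            fh.write(
                f"{locus_id}\t{fmt(rec.northern)}\t{int(rec.override_c2)}\t"
                f"{int(rec.override_c3)}\n"
            )
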