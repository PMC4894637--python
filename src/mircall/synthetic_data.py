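"""Synthetic genomes and three-strain small-RNA libraries with ground truth.

The generator emulates the statistical structure the identification criteria
assume: an AT-rich genome (GC fraction 0.23, matching the study organism),
hairpin loci whose mature arm is elevated in the suppressor mutant and
depleted in the processing mutant, star reads placed by 2-nt 3'-overhang
duplex geometry at roughly a tenth of mature abundance, non-canonical
"miRNA-like" loci with the same genetics but no hairpin context and no star,
suppressor-only siRNA clusters, and uniform degradation background of mixed
lengths.  Per-locus, per-strain counts are Poisson around
wt_depth, wt_depth*fold_up (suppressor) and wt_depth/fold_down (processing
mutant); an optional negative-binomial switch adds overdispersion but is off
by default, Poisson being the minimal model consistent with plain
fold-change criteria.

Everything derives from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .criteria import CandidateMiRNA, Classification
from .seqio import (
    EvidenceRecord,
    EvidenceTable,
    GenomeSequence,
    SmallRNARead,
    Strain,
    StrainLibrary,
    region_id,
    revcomp,
)
from .structure import assess_hairpin

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    genome_length: int = 150_000
    gc_content: float = 0.23
    n_canonical: int = 20
    n_mirna_like: int = 3
    n_background_loci: int = 5
    n_multimap_loci: int = 0  # each planted at 4 genomic copies
    fold_up_range: tuple[float, float] = (5.0, 80.0)
    fold_down_range: tuple[float, float] = (5.0, 50.0)
    wt_depth_per_locus: float = 20.0
    library_size: int = 25_000
    star_to_mature_ratio: float = 0.1
    mature_len_range: tuple[int, int] = (20, 24)
    loop_len_range: tuple[int, int] = (4, 15)
    arm_identity_range: tuple[float, float] = (0.85, 1.0)
    overhang: int = 2
    jitter_rate: float = 0.1
    jitter_max: int = 2
    background_len_range: tuple[int, int] = (15, 35)
    min_separation: int = 400
    nb_dispersion: Optional[float] = None  # negative-binomial k; None = Poisson
    chrom_id: str = "chr1"
    seed: int = 42

    def validate(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("n_canonical", "n_mirna_like", "n_background_loci",
                     "n_multimap_loci", "genome_length", "library_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fold_up_range", "fold_down_range", "mature_len_range",
                     "loop_len_range", "arm_identity_range", "background_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low must be <= high")


@dataclass
class PlantedLocus:
    locus_id: str
    kind: str  # CANONICAL, MIRNA_LIKE, SIRNA_BACKGROUND
    chrom_id: str
    strand: str
    mature_span: tuple[int, int]
    star_span: Optional[tuple[int, int]]
    fold_up: float
    fold_down: float
    copies: int = 1


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, GenomeSequence]
    libraries: dict[Strain, StrainLibrary]
    raw_reads: dict[Strain, list[str]]  # uncollapsed, library_size each
    truth: list[PlantedLocus]
    evidence: EvidenceTable

    def write(self, outdir: str | Path) -> None:
        """Write genome FASTA, per-strain FASTQ, truth GFF3/TSV, evidence TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in self.genome.values():
                fh.write(f">{chrom.chrom_id}\n")
                for i in range(0, chrom.length, 60):
                    fh.write(chrom.sequence[i:i + 60] + "\n")
        for strain, reads in self.raw_reads.items():
            with open(outdir / f"reads_{strain.value}.fastq", "w") as fh:
                for i, seq in enumerate(reads):
                    fh.write(f"@{strain.value}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        with open(outdir / "truth.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for locus in self.truth:
                s, e = locus.mature_span
                fh.write(
                    f"{locus.chrom_id}\tmircall_sim\tmature_sRNA\t{s + 1}\t{e}\t.\t"
                    f"{locus.strand}\t.\tID={locus.locus_id};kind={locus.kind}\n"
                )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "locus_id\tkind\tchrom\tstrand\tmature_start\tmature_end\t"
                "star_start\tstar_end\tfold_up\tfold_down\tcopies\n"
            )
            for locus in self.truth:
                star = locus.star_span or ("NA", "NA")
                fh.write(
                    f"{locus.locus_id}\t{locus.kind}\t{locus.chrom_id}\t"
                    f"{locus.strand}\t{locus.mature_span[0]}\t{locus.mature_span[1]}\t"
                    f"{star[0]}\t{star[1]}\t{locus.fold_up:.3f}\t"
                    f"{locus.fold_down:.3f}\t{locus.copies}\n"
                )
        from .seqio import write_evidence
        write_evidence(self.evidence, outdir / "evidence.tsv")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute bases i.i.d. so the expected identity matches."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() > identity:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


def _counts(rng: np.random.Generator, mean: float, dispersion: Optional[float]) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # NB parameterized by shape k and mean m: p = k / (k + m)
    k = dispersion
    return int(rng.negative_binomial(k, k / (k + mean)))


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate a genome, three read libraries, truth table and evidence."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    genome_arr = np.array(list(_random_seq(rng, config.genome_length, config.gc_content)))

    # --- reserve non-overlapping slots -----------------------------------
    n_multimap_copies = config.n_multimap_loci * 4
    n_slots = (
        config.n_canonical + config.n_mirna_like + config.n_background_loci
        + n_multimap_copies
    )
    slot_width = 2 * config.mature_len_range[1] + config.loop_len_range[1] + 10
    edge = 120  # keep fold contexts on-chromosome
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_slots:
        attempts += 1
        if attempts > 200 * max(n_slots, 1):
            raise ValueError(
                "could not place loci without overlap at the requested "
                "density; increase genome_length"
            )
        pos = int(rng.integers(edge, config.genome_length - edge - slot_width))
        if all(abs(pos - q) >= config.min_separation for q in positions):
            positions.append(pos)

    truth: list[PlantedLocus] = []
    evidence = EvidenceTable()
    # (strain -> list of (genomic span, strand, mean count)) per planted locus
    read_plan: list[tuple[Strain, tuple[int, int], str, float, bool]] = []
    slot_iter = iter(positions)

    def plant_hairpin(pos: int) -> tuple[tuple[int, int], tuple[int, int], str]:
        """Splice a hairpin at pos; return mature span, star READ span, strand."""
        ml = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
        loop_len = int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
        identity = rng.uniform(*config.arm_identity_range)
        mature = _random_seq(rng, ml, config.gc_content)
        arm2 = _mutate(rng, revcomp(mature), identity)
        loop = _random_seq(rng, loop_len, config.gc_content)
        mature_first = bool(rng.random() < 0.5)
        hairpin = mature + loop + arm2 if mature_first else arm2 + loop + mature
        strand = "+" if rng.random() < 0.5 else "-"
        H = len(hairpin)
        insert = hairpin if strand == "+" else revcomp(hairpin)
        genome_arr[pos:pos + H] = list(insert)
        # local (hairpin) coordinates
        if mature_first:
            mature_loc = (0, ml)
            star_loc = (ml + loop_len + config.overhang, H + config.overhang)
        else:
            mature_loc = (ml + loop_len, H)
            star_loc = (config.overhang, ml + config.overhang)

        def to_genomic(loc: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (pos + loc[0], pos + loc[1])
            return (pos + H - loc[1], pos + H - loc[0])

        return to_genomic(mature_loc), to_genomic(star_loc), strand

    # canonical hairpin loci
    for i in range(config.n_canonical):
        pos = next(slot_iter)
        fold_up = rng.uniform(*config.fold_up_range)
        fold_down = rng.uniform(*config.fold_down_range)
        mature_span, star_span, strand = plant_hairpin(pos)
        locus_id = f"sim_can_{i + 1:03d}"
        truth.append(PlantedLocus(
            locus_id, "CANONICAL", config.chrom_id, strand,
            mature_span, star_span, fold_up, fold_down,
        ))
        evidence.records[region_id(config.chrom_id, *mature_span, strand)] = (
            EvidenceRecord(northern=True)
        )
        depth = config.wt_depth_per_locus
        for strain, mean in (
            (Strain.WT, depth),
            (Strain.SUPP_MUTANT, depth * fold_up),
            (Strain.PROC_MUTANT, depth / fold_down),
        ):
            read_plan.append((strain, mature_span, strand, mean, True))
            read_plan.append(
                (strain, star_span, strand, mean * config.star_to_mature_ratio, False)
            )

    # miRNA-like loci: miRNA genetics (granted by blot evidence), no hairpin,
    # no star reads.  Contexts are redrawn until they genuinely fail the
    # hairpin call, enforcing the no-complement invariant of this class.
    for i in range(config.n_mirna_like + n_multimap_copies):
        multimap = i >= config.n_mirna_like
        if multimap and (i - config.n_mirna_like) % 4 == 0:
            group = (i - config.n_mirna_like) // 4
            shared_mature = _random_seq(
                rng,
                int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1)),
                config.gc_content,
            )
        pos = next(slot_iter)
        ml_len = (
            len(shared_mature) if multimap
            else int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        mature_span = (pos, pos + ml_len)
        for _ in range(50):
            mature = shared_mature if multimap else _random_seq(rng, ml_len, config.gc_content)
            insert = mature if strand == "+" else revcomp(mature)
            genome_arr[pos:pos + ml_len] = list(insert)
            lo = max(0, pos - 60)
            hi = min(config.genome_length, pos + ml_len + 60)
            ctx = "".join(genome_arr[lo:hi])
            if strand == "-":
                ctx = revcomp(ctx)
                span = (hi - mature_span[1], hi - mature_span[0])
            else:
                span = (mature_span[0] - lo, mature_span[1] - lo)
            _, hp = assess_hairpin(ctx, span)
            if not hp.is_hairpin:
                break
            if multimap:  # shared sequence is fixed; accept and move on
                break
        if multimap:
            locus_id = f"sim_multi_{group + 1:02d}_copy{(i - config.n_mirna_like) % 4 + 1}"
            copies = 4
        else:
            locus_id = f"sim_like_{i + 1:03d}"
            copies = 1
        truth.append(PlantedLocus(
            locus_id, "MIRNA_LIKE", config.chrom_id, strand,
            mature_span, None, 2.0, 1.0, copies=copies,
        ))
        evidence.records[region_id(config.chrom_id, *mature_span, strand)] = (
            EvidenceRecord(northern=True, override_c2=True, override_c3=True)
        )
        if not multimap or (i - config.n_mirna_like) % 4 == 0:
            depth = config.wt_depth_per_locus
            for strain, mean in (
                (Strain.WT, depth),
                (Strain.SUPP_MUTANT, depth * 2.0),
                (Strain.PROC_MUTANT, depth),
            ):
                read_plan.append((strain, mature_span, strand, mean, True))

    # suppressor-only siRNA clusters (background loci that must be rejected)
    for i in range(config.n_background_loci):
        pos = next(slot_iter)
        strand = "+" if rng.random() < 0.5 else "-"
        span = (pos, pos + 21)
        truth.append(PlantedLocus(
            f"sim_sirna_{i + 1:03d}", "SIRNA_BACKGROUND", config.chrom_id,
            strand, span, None, float("inf"), 0.0,
        ))
        read_plan.append(
            (Strain.SUPP_MUTANT, span, strand, 3 * config.wt_depth_per_locus, True)
        )

    genome_seq = "".join(genome_arr)
    genome = {config.chrom_id: GenomeSequence(config.chrom_id, genome_seq)}

    def extract(span: tuple[int, int], strand: str) -> str:
        seg = genome_seq[span[0]:span[1]]
        return seg if strand == "+" else revcomp(seg)

    # --- draw reads -------------------------------------------------------
    raw_reads: dict[Strain, list[str]] = {s: [] for s in Strain}
    for strain, span, strand, mean, jitter in read_plan:
        n = _counts(rng, mean, config.nb_dispersion)
        for _ in range(n):
            s, e = span
            if jitter and rng.random() < config.jitter_rate:
                shift = int(rng.integers(-config.jitter_max, config.jitter_max + 1))
                s, e = s + shift, e + shift
            s = max(0, s)
            e = min(config.genome_length, e)
            raw_reads[strain].append(extract((s, e), strand))

    bg_lo, bg_hi = config.background_len_range
    for strain in Strain:
        n_bg = config.library_size - len(raw_reads[strain])
        if n_bg < 0:
            raise ValueError(
                f"library_size {config.library_size} too small for planted "
                f"locus reads in strain {strain.value} "
                f"({len(raw_reads[strain])}); increase library_size"
            )
        lengths = rng.integers(bg_lo, bg_hi + 1, size=n_bg)
        starts = rng.integers(0, config.genome_length - bg_hi, size=n_bg)
        strands = rng.random(size=n_bg) < 0.5
        for ln, st, fwd in zip(lengths, starts, strands):
            raw_reads[strain].append(
                extract((int(st), int(st) + int(ln)), "+" if fwd else "-")
            )

    libraries: dict[Strain, StrainLibrary] = {}
    for strain in Strain:
        counts: dict[str, int] = {}
        for seq in raw_reads[strain]:
            counts[seq] = counts.get(seq, 0) + 1
        libraries[strain] = StrainLibrary(
            strain=strain,
            reads=[SmallRNARead(seq, c) for seq, c in sorted(counts.items())],
            n_input=len(raw_reads[strain]),
        )

    return SimulatedDataset(
        config=config,
        genome=genome,
        libraries=libraries,
        raw_reads=raw_reads,
        truth=truth,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# Recovery scoring.


@dataclass
class RecoveryReport:
    sensitivity: float
    precision: float
    confusion: dict[tuple[str, str], int]
    n_planted_canonical: int
    n_called_canonical: int
    matches: dict[str, str] = field(default_factory=dict)  # candidate -> truth


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def score_recovery(
    candidates: list[CandidateMiRNA],
    truth: list[PlantedLocus],
    min_overlap: float = 0.5,
) -> RecoveryReport:
    """Match candidates to planted loci (>= 50% reciprocal mature overlap).

    Sensitivity and precision are reported for the CANONICAL class.
    """
    matches: dict[str, str] = {}
    confusion: dict[tuple[str, str], int] = {}
    truth_called: dict[str, str] = {}
    for cand in candidates:
        span = (cand.mature_window.start, cand.mature_window.end)
        best, best_frac = None, 0.0
        for locus in truth:
            if locus.chrom_id != cand.chrom_id or locus.strand != cand.strand:
                continue
            frac = _reciprocal_overlap(span, locus.mature_span)
            if frac >= min_overlap and frac > best_frac:
                best, best_frac = locus, frac
        kind = best.kind if best else "NONE"
        confusion[(kind, cand.classification.value)] = (
            confusion.get((kind, cand.classification.value), 0) + 1
        )
        if best is not None:
            matches[cand.locus_id] = best.locus_id
            prev = truth_called.get(best.locus_id)
            if prev is None or cand.classification is Classification.CANONICAL:
                truth_called[best.locus_id] = cand.classification.value

    planted_canonical = [t for t in truth if t.kind == "CANONICAL"]
    recovered = sum(
        1 for t in planted_canonical if truth_called.get(t.locus_id) == "CANONICAL"
    )
    called_canonical = [
        c for c in candidates if c.classification is Classification.CANONICAL
    ]
    true_canonical_calls = confusion.get(("CANONICAL", "CANONICAL"), 0)
    sensitivity = recovered / len(planted_canonical) if planted_canonical else 1.0
    precision = (
        true_canonical_calls / len(called_canonical) if called_canonical else 1.0
    )
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        confusion=confusion,
        n_planted_canonical=len(planted_canonical),
        n_called_canonical=len(called_canonical),
        matches=matches,
    )
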