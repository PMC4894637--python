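"""Candidate seeding, the six identification criteria, and classification.

A putative miRNA locus is scored against six criteria:

1. mature length within 20-24 nt;
2. at least ``f_up``-fold (default 3) higher in the suppressor mutant than
   in wild type;
3. at least ``f_down``-fold (default 3) lower in the processing mutant than
   in wild type;
4. the mature resides in a hairpin-like structure;
5. a corresponding star (miRNA-5p/-3p partner) sequence exists in the reads;
6. detectable by Northern blot (experimental evidence, never computed).

A locus is VALIDATED when at least four criteria are met.  Validated loci
split into CANONICAL (hairpin and star both present, i.e. c4 AND c5) and
non-canonical MIRNA_LIKE (validated without the hairpin/star pair) — the
at-least-four rule alone cannot make that split.  Criteria 2 and 3 may be
overridden to true by blot evidence ("based on NB") when sequencing depth
fails them; the override channel is off unless the evidence table requests
it.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .mapping import PlacementSet, ReadPlacement, map_reads
from .quantify import (
    ExpressionProfile,
    FoldChangeFlags,
    LocusWindow,
    count_window,
    expression_criteria,
    load_expression_table,
    normalize,
    profiles_from_table,
)
from .seqio import (
    EvidenceRecord,
    EvidenceTable,
    GenomeSequence,
    Strain,
    StrainLibrary,
    revcomp,
    rna,
)
from .structure import (
    HairpinCall,
    StarPrediction,
    assess_hairpin,
    detect_star_reads,
    predict_star,
)

log = logging.getLogger(__name__)


class Classification(enum.Enum):
    CANONICAL = "CANONICAL"
    MIRNA_LIKE = "MIRNA_LIKE"
    REJECTED = "REJECTED"


class CriterionSource(enum.Enum):
    SEQ = "SEQ"
    NB_OVERRIDE = "NB_OVERRIDE"


@dataclass
class CriteriaVector:
    c1: bool = False
    c2: bool = False
    c3: bool = False
    c4: bool = False
    c5: bool = False
    c6: bool = False
    c2_source: CriterionSource = CriterionSource.SEQ
    c3_source: CriterionSource = CriterionSource.SEQ

    @property
    def n_met(self) -> int:
        return sum((self.c1, self.c2, self.c3, self.c4, self.c5, self.c6))

    def met(self) -> tuple[int, ...]:
        return tuple(
            i for i, flag in enumerate(
                (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6), start=1
            ) if flag
        )

    def criteria_string(self) -> str:
        """Human-readable criteria list, e.g. '1,2,3 (based on NB),6'."""
        parts = []
        for i in self.met():
            label = str(i)
            if i == 2 and self.c2_source is CriterionSource.NB_OVERRIDE:
                label += " (based on NB)"
            if i == 3 and self.c3_source is CriterionSource.NB_OVERRIDE:
                label += " (based on NB)"
            parts.append(label)
        return ",".join(parts)


@dataclass
class CandidateMiRNA:
    """A locus with its criteria vector and final class."""

    locus_id: str
    chrom_id: str
    strand: str
    mature_window: LocusWindow
    mature_sequence: str  # RNA alphabet
    arm: str  # 5p or 3p, by genomic orientation of the hairpin arms
    criteria: CriteriaVector
    classification: Classification
    fold_flags: FoldChangeFlags
    profiles: dict[str, ExpressionProfile] = field(default_factory=dict)
    hairpin: Optional[HairpinCall] = None
    star: Optional[StarPrediction] = None
    star_window: Optional[LocusWindow] = None
    multiplicity: int = 1


def evaluate_candidate(
    mature_length: int,
    fold_flags: FoldChangeFlags,
    hairpin_ok: bool,
    star_supported: bool,
    evidence: Optional[EvidenceRecord] = None,
    len_range: tuple[int, int] = (20, 24),
) -> CriteriaVector:
    """Assemble the six-criteria vector for one candidate locus."""
    cv = CriteriaVector(
        c1=len_range[0] <= mature_length <= len_range[1],
        c2=fold_flags.c2,
        c3=fold_flags.c3,
        c4=hairpin_ok,
        c5=star_supported,
        c6=bool(evidence is not None and evidence.northern is True),
    )
    if evidence is not None:
        if not cv.c2 and evidence.override_c2:
            cv.c2, cv.c2_source = True, CriterionSource.NB_OVERRIDE
        if not cv.c3 and evidence.override_c3:
            cv.c3, cv.c3_source = True, CriterionSource.NB_OVERRIDE
    return cv


def classify_candidate(
    criteria: CriteriaVector, validated_min: int = 4
) -> Classification:
    """Apply the at-least-four rule and the canonical/non-canonical split."""
    if criteria.n_met < validated_min:
        return Classification.REJECTED
    if criteria.c4 and criteria.c5:
        return Classification.CANONICAL
    return Classification.MIRNA_LIKE


# ---------------------------------------------------------------------------
# Seeding candidate loci from read clusters.


@dataclass
class SeedCluster:
    window: LocusWindow
    supp_count: int
    multiplicity: int


def seed_candidates(
    placements: PlacementSet,
    min_reads: int = 5,
    max_cluster_gap: int = 30,
    len_range: tuple[int, int] = (20, 24),
    margin: int = 5,
) -> list[SeedCluster]:
    """Seed putative mature windows from suppressor-strain read clusters.

    Same-strand suppressor-mutant placements are merged into maximal
    clusters with inter-read gap <= ``max_cluster_gap``; the cluster's modal
    read (highest suppressor count; ties to the leftmost, then
    lexicographically smallest sequence) defines the putative mature window.
    Clusters are kept when the suppressor count reaches ``min_reads`` and the
    modal read length is within ``len_range``.  The suppressor mutant is the
    discovery contrast — the strain in which miRNAs are elevated — so
    clustering it, rather than the read union, keeps wild-type background
    from chaining clusters together.
    """
    supp = placements.placements.get(Strain.SUPP_MUTANT, [])
    groups: dict[tuple[str, str], list[ReadPlacement]] = {}
    for p in supp:
        groups.setdefault((p.chrom_id, p.strand), []).append(p)

    seeds: list[SeedCluster] = []
    for (chrom, strand) in sorted(groups):
        group = sorted(groups[(chrom, strand)], key=lambda p: (p.start, p.end))
        cluster: list[ReadPlacement] = []
        cluster_end = None

        def flush():
            if not cluster:
                return
            if sum(p.count for p in cluster) < min_reads:
                return
            modal = max(cluster, key=lambda p: (p.count, -p.start, p.read_sequence))
            if not (len_range[0] <= modal.end - modal.start <= len_range[1]):
                return
            # a mature miRNA is a stacked read pile: the modal window itself
            # (with its +/- margin) must carry the required suppressor
            # support, not just the diffuse cluster around it
            total = sum(
                p.count for p in cluster
                if p.start >= modal.start - margin and p.end <= modal.end + margin
            )
            if total < min_reads:
                return
            seeds.append(SeedCluster(
                window=LocusWindow(
                    locus_id="",
                    chrom_id=chrom,
                    arm="5p",
                    start=modal.start,
                    end=modal.end,
                    strand=strand,
                    margin=margin,
                ),
                supp_count=total,
                multiplicity=modal.multiplicity,
            ))

        for p in group:
            if cluster_end is not None and p.start - cluster_end <= max_cluster_gap:
                cluster.append(p)
                cluster_end = max(cluster_end, p.end)
            else:
                flush()
                cluster = [p]
                cluster_end = p.end
        flush()
    seeds.sort(key=lambda s: (s.window.chrom_id, s.window.start, s.window.strand))
    return seeds


# ---------------------------------------------------------------------------
# End-to-end discovery.


def _context_coords(
    window: LocusWindow, genome: Mapping[str, GenomeSequence], flank: int
) -> tuple[str, int, int, tuple[int, int]]:
    """Extract the fold context in transcript (5'->3') orientation.

    Returns (context sequence, genomic ctx start, genomic ctx end, mature
    span in context coordinates).
    """
    chrom = genome[window.chrom_id]
    g_lo = max(0, window.start - flank)
    g_hi = min(chrom.length, window.end + flank)
    segment = chrom.sequence[g_lo:g_hi]
    if window.strand == "+":
        ctx = segment
        span = (window.start - g_lo, window.end - g_lo)
    else:
        ctx = revcomp(segment)
        span = (g_hi - window.end, g_hi - window.start)
    return ctx, g_lo, g_hi, span


def _ctx_to_genomic(
    span: tuple[int, int], strand: str, g_lo: int, g_hi: int
) -> tuple[int, int]:
    if strand == "+":
        return (g_lo + span[0], g_lo + span[1])
    return (g_hi - span[1], g_hi - span[0])


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _resolve_mirror_pairs(candidates: list[CandidateMiRNA]) -> list[CandidateMiRNA]:
    """Collapse opposite-strand mirror images of the same hairpin locus.

    A perfect fold-back is strand-ambiguous under exact mapping: the minus
    strand of the star arm spells the mature sequence, so the locus can be
    discovered once per strand, with each twin's predicted star lying on the
    other's mature window.  Reads with jittered 5' ends only map on the true
    strand, so the twin with the higher suppressor-mutant support in its
    mature window is kept (ties: plus strand, then leftmost).
    """

    def supp_count(c: CandidateMiRNA) -> int:
        prof = c.profiles.get(c.arm)
        return prof.raw.get(Strain.SUPP_MUTANT, 0) if prof else 0

    def spans_mirror(a: CandidateMiRNA, b: CandidateMiRNA) -> bool:
        if a.chrom_id != b.chrom_id or a.strand == b.strand:
            return False
        if a.star_window is None or b.star_window is None:
            return False
        fw = _overlap_frac(
            (a.mature_window.start, a.mature_window.end),
            (b.star_window.start, b.star_window.end),
        )
        bw = _overlap_frac(
            (b.mature_window.start, b.mature_window.end),
            (a.star_window.start, a.star_window.end),
        )
        return fw >= 0.5 and bw >= 0.5

    dropped: set[int] = set()
    for i, a in enumerate(candidates):
        if i in dropped:
            continue
        for j in range(i + 1, len(candidates)):
            if j in dropped:
                continue
            b = candidates[j]
            if not spans_mirror(a, b):
                continue
            rank_a = (supp_count(a), a.strand == "+", -a.mature_window.start)
            rank_b = (supp_count(b), b.strand == "+", -b.mature_window.start)
            dropped.add(j if rank_a >= rank_b else i)
    return [c for i, c in enumerate(candidates) if i not in dropped]


def discover_mirnas(
    genome: Mapping[str, GenomeSequence],
    libraries: Mapping[Strain, StrainLibrary],
    evidence: Optional[EvidenceTable] = None,
    *,
    k: int = 12,
    margin: int = 5,
    f_up: float = 3.0,
    f_down: float = 3.0,
    len_range: tuple[int, int] = (20, 24),
    min_loop: int = 3,
    theta_pair: float = 0.6,
    max_loop: int = 50,
    max_bulge: int = 2,
    flank: int = 60,
    overhang: int = 2,
    star_tolerance: int = 2,
    min_star_reads: int = 1,
    seed_min_reads: int = 5,
    max_cluster_gap: int = 30,
    validated_min: int = 4,
    placements: Optional[PlacementSet] = None,
) -> list[CandidateMiRNA]:
    """Run the full discovery pipeline: map, seed, quantify, fold, classify.

    Deterministic for fixed inputs; candidates are returned sorted by
    (chromosome, start).  ``placements`` may be supplied to reuse an
    existing mapping.
    """
    missing = [s for s in Strain if s not in libraries]
    if missing:
        raise ValueError(f"missing strain libraries: {[s.value for s in missing]}")
    if placements is None:
        placements = map_reads(libraries, genome, k=k)
    seeds = seed_candidates(
        placements,
        min_reads=seed_min_reads,
        max_cluster_gap=max_cluster_gap,
        len_range=len_range,
        margin=margin,
    )

    accepted: list[CandidateMiRNA] = []
    claimed: list[tuple[str, str, tuple[int, int]]] = []  # chrom, strand, span
    for seed in seeds:
        w = seed.window
        span = (w.start, w.end)
        if any(
            chrom == w.chrom_id and strand == w.strand
            and _overlap_frac(span, other) >= 0.5
            for chrom, strand, other in claimed
        ):
            continue

        ctx, g_lo, g_hi, mature_ctx = _context_coords(w, genome, flank)
        fold, hairpin = assess_hairpin(
            ctx, mature_ctx,
            theta_pair=theta_pair, max_loop=max_loop, min_loop=min_loop,
            max_bulge=max_bulge,
        )
        arm = "5p"
        if hairpin.mature_is_5p is not None:
            # mature_is_5p is in transcript orientation, which the context
            # extraction already aligned with the genomic strand.
            arm = "5p" if hairpin.mature_is_5p else "3p"

        star = None
        star_window = None
        star_genomic = None
        if hairpin.is_hairpin:
            star = predict_star(fold, hairpin, overhang=overhang)
            star_genomic = _ctx_to_genomic(star.star_span, w.strand, g_lo, g_hi)
            star = detect_star_reads(
                placements, star, w.chrom_id, w.strand, star_genomic,
                tolerance=star_tolerance, min_star_reads=min_star_reads,
            )
            star_window = LocusWindow(
                locus_id="", chrom_id=w.chrom_id,
                arm="3p" if arm == "5p" else "5p",
                start=star_genomic[0], end=star_genomic[1],
                strand=w.strand, margin=margin,
            )

        chrom_len = genome[w.chrom_id].length
        profiles: dict[str, ExpressionProfile] = {}
        mature_profile = normalize(
            count_window(placements, w, chrom_len),
            placements.total_aligned, locus_id="", arm=arm,
        )
        profiles[arm] = mature_profile
        if star_window is not None:
            profiles[star_window.arm] = normalize(
                count_window(placements, star_window, chrom_len),
                placements.total_aligned, locus_id="", arm=star_window.arm,
            )
        flags = expression_criteria(list(profiles.values()), f_up=f_up, f_down=f_down)

        ev = None
        if evidence is not None:
            ev = evidence.match_region(w.chrom_id, w.start, w.end, w.strand)

        cv = evaluate_candidate(
            mature_length=w.length,
            fold_flags=flags,
            hairpin_ok=hairpin.is_hairpin,
            star_supported=bool(star is not None and star.supported),
            evidence=ev,
            len_range=len_range,
        )
        classification = classify_candidate(cv, validated_min=validated_min)

        if w.strand == "+":
            mature_seq = genome[w.chrom_id].sequence[w.start:w.end]
        else:
            mature_seq = revcomp(genome[w.chrom_id].sequence[w.start:w.end])

        accepted.append(CandidateMiRNA(
            locus_id="",
            chrom_id=w.chrom_id,
            strand=w.strand,
            mature_window=w,
            mature_sequence=rna(mature_seq),
            arm=arm,
            criteria=cv,
            classification=classification,
            fold_flags=flags,
            profiles=profiles,
            hairpin=hairpin,
            star=star,
            star_window=star_window,
            multiplicity=seed.multiplicity,
        ))
        claimed.append((w.chrom_id, w.strand, span))
        if star_genomic is not None:
            claimed.append((w.chrom_id, w.strand, star_genomic))

    accepted = _resolve_mirror_pairs(accepted)
    accepted.sort(key=lambda c: (c.chrom_id, c.mature_window.start, c.strand))
    for i, cand in enumerate(accepted, start=1):
        cand.locus_id = f"locus_{i:04d}"
        cand.mature_window = LocusWindow(
            locus_id=cand.locus_id,
            chrom_id=cand.mature_window.chrom_id,
            arm=cand.arm,
            start=cand.mature_window.start,
            end=cand.mature_window.end,
            strand=cand.mature_window.strand,
            margin=cand.mature_window.margin,
        )
        cand.fold_flags.locus_id = cand.locus_id
        for prof in cand.profiles.values():
            prof.locus_id = cand.locus_id
    return accepted


# ---------------------------------------------------------------------------
# Replay mode: classify from printed per-arm relative expression and flags.


@dataclass
class ReplayResult:
    locus_id: str
    criteria: CriteriaVector
    classification: Classification
    fold_flags: FoldChangeFlags
    known: bool
    mature_sequence: str
    mature_length: int


def replay_classification(
    table: pd.DataFrame | str | Path,
    f_up: float = 3.0,
    f_down: float = 3.0,
    len_range: tuple[int, int] = (20, 24),
    validated_min: int = 4,
) -> list[ReplayResult]:
    """Classify loci from an externally supplied relative-expression table.

    The table (TSV path or DataFrame; decimal commas accepted) carries one
    row per arm with columns locus_id, arm, sequence, wt, proc_mutant,
    supp_mutant, and per-locus flags hairpin/star/northern (plus optional
    override_c2/override_c3 and a `known` marker for previously reported
    loci).  The first-listed arm of each locus is taken as the annotated
    mature.
    """
    if not isinstance(table, pd.DataFrame):
        table = load_expression_table(table)
    profiles = profiles_from_table(table)

    results: list[ReplayResult] = []
    for locus_id in table["locus_id"].drop_duplicates():
        rows = table[table["locus_id"] == locus_id]
        first = rows.iloc[0]
        flags = expression_criteria(profiles[locus_id], f_up=f_up, f_down=f_down)
        ev = EvidenceRecord(
            northern=bool(int(first.get("northern", 0))),
            override_c2=bool(int(first.get("override_c2", 0))),
            override_c3=bool(int(first.get("override_c3", 0))),
        )
        mature_seq = str(first.get("sequence", ""))
        cv = evaluate_candidate(
            mature_length=len(mature_seq),
            fold_flags=flags,
            hairpin_ok=bool(int(first.get("hairpin", 0))),
            star_supported=bool(int(first.get("star", 0))),
            evidence=ev,
            len_range=len_range,
        )
        results.append(ReplayResult(
            locus_id=locus_id,
            criteria=cv,
            classification=classify_candidate(cv, validated_min=validated_min),
            fold_flags=flags,
            known=bool(int(first.get("known", 0))),
            mature_sequence=mature_seq,
            mature_length=len(mature_seq),
        ))
    return results


def bundled_replay_table() -> Path:
    """Path to the bundled replay fixture (the published worked example)."""
    return Path(__file__).parent / "data" / "dicty_mirna_replay.tsv"
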