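"""Windowed read counting, library-size normalization and fold-change flags.

Reads are counted in a window extended by a +/- margin (default 5 nt) around
a locus arm: a placement counts, with its full collapsed count at every
placement, iff its strand matches and it is fully contained in the extended
window.  Raw counts become reads-per-million (RPM) over the per-strain
aligned totals, and per-strain values relative to wild type.

The two expression criteria compare strains by plain fold ratios:

* c2 — suppressor-mutant up at least ``f_up``-fold over wild type,
* c3 — processing-mutant down at least ``f_down``-fold under wild type,

with the zero-denominator convention x/0 = +inf for x > 0 and 0/0 = 0, and
locus-level folds taken as the MAXIMUM over the arms of a locus.  Both
choices are required to reproduce the published criteria assignments of the
worked example (loci whose processing-mutant signal vanishes entirely, and a
locus whose 5p arm alone drops under 3-fold while its 3p arm passes).
Fold ratios are invariant to a common per-row scale, so the same operation
accepts externally supplied relative-expression values in place of RPM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .mapping import PlacementSet
from .seqio import Strain

log = logging.getLogger(__name__)

ARMS = ("5p", "3p")


@dataclass(frozen=True)
class LocusWindow:
    """A mature-arm span (0-based half-open) with a counting margin."""

    locus_id: str
    chrom_id: str
    arm: str  # "5p" or "3p"
    start: int
    end: int
    strand: str
    margin: int = 5

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionProfile:
    """Per-strain abundance of one locus arm.

    ``rel_to_wt`` is None (undefined) when the wild-type RPM is zero.
    """

    locus_id: str
    arm: str
    raw: dict[Strain, int] = field(default_factory=dict)
    rpm: dict[Strain, float] = field(default_factory=dict)
    rel_to_wt: dict[Strain, Optional[float]] = field(default_factory=dict)


@dataclass
class FoldChangeFlags:
    """Locus-level fold changes and the two expression criteria."""

    locus_id: str
    fold_up: float
    fold_down: float
    c2: bool
    c3: bool


def count_window(
    placements: PlacementSet,
    window: LocusWindow,
    chrom_length: Optional[int] = None,
) -> dict[Strain, int]:
    """Count strand-matched placements fully contained in window +/- margin."""
    lo = window.start - window.margin
    hi = window.end + window.margin
    if lo < 0 or (chrom_length is not None and hi > chrom_length):
        log.info("window %s clipped to chromosome bounds", window.locus_id)
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
    counts: dict[Strain, int] = {}
    for strain in placements.placements:
        counts[strain] = sum(
            p.count
            for p in placements.contained(strain, window.chrom_id, window.strand, lo, hi)
        )
    return counts


def normalize(
    raw: Mapping[Strain, int],
    totals: Mapping[Strain, int],
    locus_id: str = "",
    arm: str = "",
) -> ExpressionProfile:
    """Convert raw window counts to RPM and wild-type-relative values."""
    profile = ExpressionProfile(locus_id=locus_id, arm=arm)
    for strain, count in raw.items():
        total = totals.get(strain, 0)
        if total == 0:
            if count > 0:
                raise ValueError(
                    f"{locus_id}/{arm}: strain {strain.value} has counted reads "
                    "but total_aligned == 0"
                )
            rpm = 0.0
        else:
            rpm = 1e6 * count / total
        profile.raw[strain] = count
        profile.rpm[strain] = rpm
    wt = profile.rpm.get(Strain.WT, 0.0)
    for strain in profile.rpm:
        profile.rel_to_wt[strain] = profile.rpm[strain] / wt if wt > 0 else None
    return profile


def _ratio(num: float, den: float) -> float:
    """x/0 = +inf for x > 0; 0/0 = 0.  No pseudocounts."""
    if den > 0:
        return num / den
    return math.inf if num > 0 else 0.0


def expression_criteria(
    profiles: Sequence[ExpressionProfile],
    f_up: float = 3.0,
    f_down: float = 3.0,
) -> FoldChangeFlags:
    """Evaluate the two fold-change criteria over the arms of one locus.

    Locus-level ``fold_up`` and ``fold_down`` are the maximum over arms of
    the per-arm ratios RPM(suppressor)/RPM(wt) and RPM(wt)/RPM(processing
    mutant) respectively.
    """
    if not profiles:
        raise ValueError("at least one arm profile is required")
    fold_up = 0.0
    fold_down = 0.0
    for prof in profiles:
        wt = prof.rpm.get(Strain.WT, 0.0)
        supp = prof.rpm.get(Strain.SUPP_MUTANT, 0.0)
        proc = prof.rpm.get(Strain.PROC_MUTANT, 0.0)
        fold_up = max(fold_up, _ratio(supp, wt))
        fold_down = max(fold_down, _ratio(wt, proc))
    return FoldChangeFlags(
        locus_id=profiles[0].locus_id,
        fold_up=fold_up,
        fold_down=fold_down,
        c2=fold_up >= f_up,
        c3=fold_down >= f_down,
    )


def parse_decimal(value) -> float:
    """Parse a decimal that may use a comma separator ('915,13' -> 915.13)."""
    if isinstance(value, (int, float)):
        return float(value)
    return float(str(value).strip().replace(",", "."))


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """Load a relative-expression TSV (replay input).

    Required columns: locus_id, arm, wt, proc_mutant, supp_mutant; numbers
    may use decimal commas.  Optional columns (sequence and per-locus flags)
    are passed through unchanged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"locus_id", "arm", "wt", "proc_mutant", "supp_mutant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("wt", "proc_mutant", "supp_mutant"):
        df[col] = df[col].map(parse_decimal)
    for col in ("hairpin", "star", "northern", "override_c2", "override_c3", "known"):
        if col in df.columns:
            df[col] = df[col].fillna("0").astype(int)
    return df


def profiles_from_table(df: pd.DataFrame) -> dict[str, list[ExpressionProfile]]:
    """Build per-locus arm profiles from externally supplied relative values.

    The given values are used in place of RPM; fold ratios are unaffected by
    the unknown common scale.
    """
    out: dict[str, list[ExpressionProfile]] = {}
    for _, row in df.iterrows():
        prof = ExpressionProfile(locus_id=row["locus_id"], arm=row["arm"])
        prof.rpm = {
            Strain.WT: float(row["wt"]),
            Strain.PROC_MUTANT: float(row["proc_mutant"]),
            Strain.SUPP_MUTANT: float(row["supp_mutant"]),
        }
        wt = prof.rpm[Strain.WT]
        prof.rel_to_wt = {
            s: (v / wt if wt > 0 else None) for s, v in prof.rpm.items()
        }
        out.setdefault(row["locus_id"], []).append(prof)
    return out
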