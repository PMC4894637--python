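"""RNA secondary structure: maximum-pairing folding and hairpin geometry.

Folding uses the Nussinov dynamic program — maximize the number of nested
{AU, GC, GU} base pairs subject to a minimum hairpin-loop length (default
3 nt).  Maximum pairing is a deliberately simple objective: the downstream
hairpin test asks only whether the mature small RNA sits on one arm of a
fold-back stem, a shape question that does not need thermodynamic (Turner)
energies.  The optimum is massively degenerate in AT-rich sequence, so the
traceback is deterministic and can be biased toward structures that pair a
span of interest against its flanks (see :func:`fold_nussinov`).

The hairpin call requires a dominant one-sided stem: among the mature's
paired bases, the largest subset whose partners all lie on one side of the
mature span (nestedness then forces the partners into one ordered run) must
cover at least ``theta_pair`` of the mature, and the loop enclosed by the
innermost stem pair must have an admissible length.  Scoring the dominant
run rather than all partners makes the call robust to stray off-stem pairs
that a maximum-pairing objective happily adds in AT-rich sequence.

Star prediction applies standard Dicer/Drosha duplex geometry: the partner
arm of the mature, offset so that both strands of the ~21-bp duplex carry
an ``overhang``-nt (default 2) 3' overhang.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mapping import PlacementSet

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for a, b in (("A", "U"), ("G", "C"), ("G", "U")):
    _PAIRABLE[_BASE_INDEX[a], _BASE_INDEX[b]] = True
    _PAIRABLE[_BASE_INDEX[b], _BASE_INDEX[a]] = True


@dataclass(frozen=True)
class FoldResult:
    """One optimal maximum-pairing structure.

    ``pairs`` are 0-based (i, j) with i < j, nested, each index in at most
    one pair.  ``score`` is the number of pairs.
    """

    sequence: str  # RNA alphabet
    pairs: tuple[tuple[int, int], ...]
    score: int
    dotbracket: str

    def partner_table(self) -> list[Optional[int]]:
        table: list[Optional[int]] = [None] * len(self.sequence)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def vienna(self) -> str:
        """Plain-text fold output: sequence line + structure line."""
        return f"{self.sequence}\n{self.dotbracket}"


@dataclass
class HairpinCall:
    """Decision on whether a mature span sits on one arm of a hairpin stem."""

    locus_id: str
    is_hairpin: bool
    mature_span: tuple[int, int]
    paired_fraction_of_mature: float
    opposite_arm_span: Optional[tuple[int, int]]
    loop_length: Optional[int]
    stem_partners: dict[int, int]  # mature index -> partner, dominant run only
    mature_is_5p: Optional[bool] = None


@dataclass
class StarPrediction:
    """Predicted (and optionally read-supported) star-arm window."""

    locus_id: str
    star_span: tuple[int, int]  # context coordinates unless mapped genomic
    overhang: int
    supported: bool = False
    supporting_reads: int = 0


def fold_nussinov(
    sequence: str,
    min_loop: int = 3,
    prefer_span: Optional[tuple[int, int]] = None,
) -> FoldResult:
    """Fold a sequence by the Nussinov maximum-pairing recursion.

    The DP runs over anti-diagonals with numpy so that contexts of a few
    hundred nucleotides fold in milliseconds; the traceback then recovers
    one optimal structure.

    The maximum-pairing optimum is massively degenerate, especially in
    AT-rich sequence where almost any base finds a partner.  ``prefer_span``
    selects among the co-optimal structures: the DP then lexicographically
    maximizes (total pairs, pairs crossing between the span and the rest of
    the sequence), so that when the span can sit on one arm of a duplex in
    SOME optimal structure, the returned structure realizes it.  The score
    (total pairs) is identical with or without a preference span.  Remaining
    ties break deterministically: pairing the interval ends is preferred
    over bifurcation, then the largest admissible bifurcation partner.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    try:
        idx = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character in sequence: {exc}") from exc
    can = _PAIRABLE[idx[:, None], idx[None, :]]

    # Combined objective: (pairs << SHIFT) + cross-span pairs.  The secondary
    # term is bounded by the span length (< 2**SHIFT), so the lexicographic
    # maximum preserves the maximum-pairing score exactly.
    SHIFT = 10
    if prefer_span is not None:
        lo, hi = prefer_span
        in_span = np.zeros(n, dtype=bool)
        in_span[lo:hi] = True
        bonus = (in_span[:, None] ^ in_span[None, :]).astype(np.int32)
        if hi - lo >= (1 << SHIFT):
            raise ValueError("prefer_span too long")
    else:
        bonus = np.zeros((n, n), dtype=np.int32)
    unit = np.int32(1 << SHIFT)

    # diag[d][i] == best combined value on seq[i .. i+d]
    diag: list[np.ndarray] = [np.zeros(n - d, dtype=np.int32) for d in range(n)]
    for d in range(1, n):
        m = n - d
        best = diag[d - 1][1:1 + m].copy()  # leave i unpaired
        for t in range(1, d):  # bifurcation seq[i..i+t] | seq[i+t+1..i+d]
            np.maximum(best, diag[t][0:m] + diag[d - 1 - t][t + 1:t + 1 + m], out=best)
        if d > min_loop:  # pair i with i+d
            i_arr = np.arange(m)
            inner = diag[d - 2][1:1 + m] if d >= 2 else np.zeros(m, dtype=np.int32)
            gain = unit + bonus[i_arr, i_arr + d]
            cand = np.where(can[i_arr, i_arr + d], inner + gain, -1).astype(np.int32)
            np.maximum(best, cand, out=best)
        diag[d][:] = best

    dp = np.zeros((n, n), dtype=np.int32)
    for d in range(1, n):
        ii = np.arange(n - d)
        dp[ii, ii + d] = diag[d]

    def val(i: int, j: int) -> int:
        return int(dp[i, j]) if i <= j else 0

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = val(i, j)
            if target == 0:
                break
            # Prefer pairing the interval ends (extends helices outermost-in).
            if (
                j - i > min_loop and can[i, j]
                and target == int(unit) + int(bonus[i, j]) + val(i + 1, j - 1)
            ):
                pairs.append((i, j))
                i, j = i + 1, j - 1
                continue
            paired = False
            for k in range(j - 1, i + min_loop, -1):
                if can[i, k] and target == (
                    int(unit) + int(bonus[i, k]) + val(i + 1, k - 1) + val(k + 1, j)
                ):
                    pairs.append((i, k))
                    stack.append((k + 1, j))
                    j = k - 1
                    i += 1
                    paired = True
                    break
            if not paired:
                i += 1
    pairs.sort()
    dots = ["."] * n
    for i, j in pairs:
        dots[i], dots[j] = "(", ")"
    return FoldResult(
        sequence=seq, pairs=tuple(pairs), score=len(pairs), dotbracket="".join(dots)
    )


def _best_stem_run(
    side: dict[int, int], max_bulge: int
) -> dict[int, int]:
    """Longest sub-run of one-sided pairs with bulges bounded on both strands.

    ``side`` maps mature index -> partner, all partners on one side of the
    mature (nestedness then makes partners monotone in the mature index).
    Consecutive stem pairs may skip at most ``max_bulge`` bases on either
    strand; larger interruptions split the run.
    """
    if not side:
        return {}
    items = sorted(side.items())
    best: list[tuple[int, int]] = []
    current: list[tuple[int, int]] = [items[0]]
    for (m0, p0), (m1, p1) in zip(items, items[1:]):
        if (m1 - m0 - 1) <= max_bulge and (abs(p0 - p1) - 1) <= max_bulge:
            current.append((m1, p1))
        else:
            if len(current) > len(best):
                best = current
            current = [(m1, p1)]
    if len(current) > len(best):
        best = current
    return dict(best)


def call_hairpin(
    fold: FoldResult,
    mature_span: tuple[int, int],
    theta_pair: float = 0.6,
    max_loop: int = 50,
    min_loop: int = 3,
    max_bulge: int = 5,
    locus_id: str = "",
) -> HairpinCall:
    """Decide the hairpin criterion for a mature span within a folded context."""
    s, e = mature_span
    n = len(fold.sequence)
    if not (0 <= s < e <= n):
        raise ValueError(f"mature span {mature_span} outside context of length {n}")
    partner = fold.partner_table()

    left_side: dict[int, int] = {}
    right_side: dict[int, int] = {}
    for m in range(s, e):
        p = partner[m]
        if p is None:
            continue
        if p < s:
            left_side[m] = p
        elif p >= e:
            right_side[m] = p
    left_run = _best_stem_run(left_side, max_bulge)
    right_run = _best_stem_run(right_side, max_bulge)
    run = right_run if len(right_run) >= len(left_run) else left_run
    fraction = len(run) / (e - s)

    opposite: Optional[tuple[int, int]] = None
    loop: Optional[int] = None
    mature_is_5p: Optional[bool] = None
    if run:
        partners = sorted(run.values())
        opposite = (partners[0], partners[-1] + 1)
        if run is right_run:
            mature_is_5p = True
            inner_m = max(run)
            loop = run[inner_m] - inner_m - 1
        else:
            mature_is_5p = False
            inner_m = min(run)
            loop = inner_m - run[inner_m] - 1
    is_hairpin = (
        fraction >= theta_pair
        and loop is not None
        and min_loop <= loop <= max_loop
    )
    return HairpinCall(
        locus_id=locus_id or "",
        is_hairpin=is_hairpin,
        mature_span=mature_span,
        paired_fraction_of_mature=fraction,
        opposite_arm_span=opposite,
        loop_length=loop,
        stem_partners=dict(sorted(run.items())),
        mature_is_5p=mature_is_5p,
    )


def assess_hairpin(
    context: str,
    mature_span: tuple[int, int],
    theta_pair: float = 0.6,
    max_loop: int = 50,
    min_loop: int = 3,
    max_bulge: int = 2,
    max_wobble: int = 2,
    locus_id: str = "",
) -> tuple[FoldResult, HairpinCall]:
    """Two-stage hairpin assessment: locate the arm by folding, then verify.

    Stage one folds the full context — preferring, among the massively
    degenerate maximum-pairing optima, structures that pair the mature
    against its flanks — and takes the dominant stem run as the putative
    opposite arm.  Stage two verifies that single arm hypothesis: the stem
    anti-diagonal implied by the run is rescanned drift-free (shifted by at
    most ``max_bulge`` nt), counting {AU, GC, GU} pairs of the mature
    against the opposite strand position by position.  The verified
    fraction, loop length and stem partners replace the stage-one values.

    Splitting location from verification is what gives the call its
    accuracy on both sides: a near-complementary planted arm passes the
    fixed-diagonal rescan even where the global fold fragments the stem
    across co-optimal helices, while background sequence must show dense
    complementarity at one specific offset rather than the best of every
    bulged alternative the fold explored.

    Returns the stage-one fold (for reporting) and the final hairpin call
    in full-context coordinates.
    """
    s, e = mature_span
    seq = context.upper().replace("T", "U")
    n = len(seq)
    fold1 = fold_nussinov(context, min_loop=min_loop, prefer_span=mature_span)
    hp1 = call_hairpin(
        fold1, mature_span,
        theta_pair=theta_pair, max_loop=max_loop, min_loop=min_loop,
        max_bulge=max_bulge, locus_id=locus_id,
    )
    if not hp1.stem_partners:
        return fold1, hp1

    idx = [_BASE_INDEX[c] for c in seq]
    on_right = next(iter(hp1.stem_partners.values())) >= e
    diagonals = sorted({m + p for m, p in hp1.stem_partners.items()})
    center = diagonals[len(diagonals) // 2]
    best_run: dict[int, int] = {}
    for c in range(center - max_bulge, center + max_bulge + 1):
        run = {}
        wobbles = 0
        for m in range(s, e):
            p = c - m
            if not (0 <= p < n):
                continue
            if (on_right and p < e) or (not on_right and p >= s):
                continue
            if _PAIRABLE[idx[m], idx[p]]:
                # a fold-back arm is a near-exact reverse complement, so the
                # stem must be predominantly Watson-Crick; G.U wobbles beyond
                # max_wobble do not count toward the verified run
                if {idx[m], idx[p]} == {2, 3}:  # G with U
                    if wobbles >= max_wobble:
                        continue
                    wobbles += 1
                run[m] = p
        if len(run) > len(best_run):
            best_run = run
    fraction = len(best_run) / (e - s)

    opposite = None
    loop = None
    if best_run:
        partners = sorted(best_run.values())
        opposite = (partners[0], partners[-1] + 1)
        if on_right:
            inner_m = max(best_run)
            loop = best_run[inner_m] - inner_m - 1
        else:
            inner_m = min(best_run)
            loop = inner_m - best_run[inner_m] - 1
    is_hairpin = (
        fraction >= theta_pair
        and loop is not None
        and min_loop <= loop <= max_loop
    )
    return fold1, HairpinCall(
        locus_id=locus_id,
        is_hairpin=is_hairpin,
        mature_span=mature_span,
        paired_fraction_of_mature=fraction,
        opposite_arm_span=opposite,
        loop_length=loop,
        stem_partners=dict(sorted(best_run.items())),
        mature_is_5p=on_right,
    )


def predict_star(
    fold: FoldResult,
    hairpin: HairpinCall,
    overhang: int = 2,
) -> StarPrediction:
    """Predict the star-arm window (context coordinates) from stem geometry.

    The star 3' end extends ``overhang`` nt past the partner of the mature's
    5' end; the star 5' end pairs the base ``overhang`` nt inside the
    mature's 3' end.  Unpaired mature end bases are handled by linear
    extrapolation from the nearest stem pair, which is exact for
    substitution-only stem imperfections.
    """
    if not hairpin.is_hairpin:
        raise ValueError("predict_star requires a positive hairpin call")
    run = hairpin.stem_partners
    s, e = hairpin.mature_span
    n = len(fold.sequence)

    # 3' end of the star: partner of the mature 5' end, plus the overhang.
    i5 = min(run)
    right_incl = run[i5] + (i5 - s) + overhang

    # 5' end of the star: partner of the base `overhang` inside the mature 3' end.
    q_target = e - 1 - overhang
    q = max((m for m in run if m <= q_target), default=None)
    if q is None:
        q = min(run)
    left = run[q] - (q_target - q)

    lo, hi = min(left, right_incl), max(left, right_incl) + 1
    lo = max(lo, 0)
    hi = min(hi, n)
    return StarPrediction(
        locus_id=hairpin.locus_id, star_span=(lo, hi), overhang=overhang
    )


def detect_star_reads(
    placements: PlacementSet,
    star: StarPrediction,
    chrom: str,
    strand: str,
    genomic_span: tuple[int, int],
    tolerance: int = 2,
    min_star_reads: int = 1,
) -> StarPrediction:
    """Set the star-support flag from sequenced reads at the star window.

    A placement supports the star if, in any strain, it lies on the same
    strand with BOTH ends within ``tolerance`` nt of the predicted star
    ends — a star read is a processing product at the predicted
    coordinates, not an arbitrary fragment inside the window.
    """
    lo = genomic_span[0] - tolerance
    hi = genomic_span[1] + tolerance
    support = 0
    for strain in placements.placements:
        support += sum(
            p.count
            for p in placements.contained(strain, chrom, strand, lo, hi)
            if abs(p.start - genomic_span[0]) <= tolerance
            and abs(p.end - genomic_span[1]) <= tolerance
        )
    star.supported = support >= min_star_reads
    star.supporting_reads = support
    return star
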