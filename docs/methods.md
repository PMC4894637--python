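# Methods

This note records the models, parameter choices and numerical conventions
behind `mircall`, and what the synthetic benchmark does and does not show.

## Read handling and mapping

Reads are collapsed to unique sequences at load time after a permissive
[15, 40] nt prefilter. The prefilter is wider than the 20–24 nt mature
criterion on purpose: background and degradation reads must reach the
classifier so that criterion 1 is a classification decision, not a parsing
side effect. Reads containing N are dropped (an exact mapper cannot place
them); drop counts are logged. The internal alphabet is DNA; mature
sequences are reported in the RNA alphabet.

Mapping is exact, full-length and ungapped on both strands, seeded by a
k-mer index (k = 12) with full-length verification. Desk-scale small-RNA
calling does not need mismatch tolerance, and exactness admits a clean
independent oracle (a naive sliding-window scan, used in the tests). Every
occurrence of a multi-mapping read is reported and counted at full weight;
each placement carries the read's total occurrence count (`multiplicity`)
so repeat-derived candidates stay identifiable. The RPM denominator
`total_aligned` counts each aligned read once, regardless of how many
places it maps, because it is a library-size quantity.

## Quantification and the expression criteria

A placement is counted toward a locus arm iff it lies, strand-matched,
fully within the arm window extended by ±5 nt (`margin`). Counts become
reads per million aligned; fold changes are RPM(suppressor)/RPM(wt) and
RPM(wt)/RPM(processing mutant), with x/0 = +∞ for x > 0 and 0/0 = 0 and no
pseudocounts — the convention required to reproduce the published criteria
assignments for loci whose processing-mutant signal is zero. Locus-level
folds are the maximum over arms: in the worked example one locus passes
criterion 3 only through its 3p arm (its 5p arm drops just 1.78-fold).
Fold ratios are invariant to a common per-row scale, so externally supplied
relative-expression values (replay mode) can stand in for RPM; absolute
wild-type-relative values are not comparable across sources and are not an
output the package vouches for.

## Secondary structure

Folding is the Nussinov maximum-pairing dynamic program: maximize the
number of nested {AU, GC, GU} pairs with a minimum loop of 3 nt.
Free-energy minimization is deliberately out of scope — the pipeline asks a
shape question (does the mature sit on one arm of a fold-back stem?), not a
stability question. The DP runs over anti-diagonals with numpy; a ~140 nt
context folds in milliseconds.

Two numerical facts shaped the design:

1. **The maximum-pairing optimum is massively degenerate** in AT-rich
   sequence (the genome simulated here is 23% GC): almost every base can
   pair somewhere, and many co-optimal structures exist. The traceback is
   therefore deterministic and, when given a span of interest, the DP
   lexicographically maximizes (total pairs, pairs crossing between the
   span and the rest of the context) so that a realizable mature/arm duplex
   is actually realized in the returned structure. The score is identical
   with or without the preference. Remaining ties prefer pairing the
   interval ends, then the largest admissible bifurcation partner.
2. **A single realized structure is still an arbitrary pick among optima**,
   so the pipeline's hairpin decision is two-staged (`assess_hairpin`):
   stage one folds the full context and takes the dominant one-sided,
   bulge-bounded run of mature-base partners as the arm hypothesis; stage
   two rescans that single stem anti-diagonal (shifted by at most
   `max_bulge` = 2 nt) counting pairs position by position, capping G·U
   wobbles at `max_wobble` = 2 since a fold-back arm is a near-exact
   reverse complement. The call is positive when the verified run covers at
   least `theta_pair` = 0.6 of the mature and the enclosed loop is within
   [3, 50] nt.

Splitting location from verification gives the call its accuracy on both
sides: a planted arm of ≥ 85% identity passes the fixed-diagonal rescan in
≥ 95% of cases even where the global fold fragments the stem, while
background sequence must show dense complementarity at one specific offset.
The residual false-positive rate on shuffled AT-rich contexts is however
substantial (roughly one in four at these thresholds; the test suite
asserts a ≥ 70% rejection rate): with {AU, GC, GU} pairing at 23% GC, a
random 21-mer finds a ≥ 60%-complementary window nearby surprisingly often.
This is a genuine limitation of pairing-count objectives in AT-rich
genomes, and it is why the canonical class is additionally gated by
criterion 5 (below) rather than by structure alone. A consequence of the
drift-free rescan is that arms with true insertion bulges are penalized;
the star-geometry code (`predict_star`) itself handles bulged stems, and
`call_hairpin` on a fold tolerates them through its bulge-bounded runs.

## Star prediction and support

The star span applies canonical Dicer duplex geometry: the partner arm of
the mature offset so both duplex strands carry a 2-nt 3′ overhang
(`overhang`, configurable). Unpaired mature end bases are handled by linear
extrapolation from the nearest stem pair, which is exact for
substitution-only stem imperfections; on perfect stems the mature↔star
mapping is an involution (tested). A star is *supported* (criterion 5) when
at least `min_star_reads` = 1 placement in any strain lies on the same
strand with both ends within `star_tolerance` = 2 nt of the predicted star
ends. End-wise agreement, rather than containment in the window, encodes
that a star read is a processing product at predicted coordinates, not an
arbitrary fragment; it is also what keeps uniform background from
certifying spurious stars.

## Seeding and locus assembly

Candidate windows are seeded from suppressor-strain placements only — the
discovery contrast, where miRNAs are elevated — clustered with an
inter-read gap ≤ 30 nt. Clustering the three-strain union instead would
chain wild-type background reads genome-wide at realistic densities. The
cluster's modal read defines the putative mature window; the cluster is
kept when that modal window (± margin) itself carries ≥ 5 suppressor reads
and the modal length is 20–24 nt. Requiring the stacked window, not the
diffuse cluster, to carry the support encodes that a mature miRNA is a read
pile with a defined 5′ end.

Mature and star arms of one hairpin fall in one cluster (loop ≤ 15 nt at
gap 30), so each hairpin seeds once, as the more abundant arm. A perfect
fold-back is strand-ambiguous under exact mapping — the minus strand of the
star arm spells the mature sequence — so a locus can be discovered once per
strand, each twin's predicted star lying on the other's mature window. Such
mirror pairs are collapsed to the twin with more suppressor support in its
mature window; reads with jittered 5′ ends map only on the true strand and
break the tie in its favour.

5p/3p labels follow the genomic orientation of the hairpin arms in
transcript direction. Northern-blot evidence attaches to candidates either
by exact locus id or by ≥ 50% reciprocal overlap with a region-keyed entry
(`chrom:start-end(strand)`); evidence may carry per-criterion overrides,
reproducing the published "(based on NB)" annotation for loci whose
sequencing depth fails criteria 2/3. Overrides never fire when the
sequencing numbers already pass.

## Classification

Validated = at least 4 of the 6 criteria (configurable `validated_min`).
Canonical additionally requires c4 ∧ c5; the at-least-four rule alone
cannot separate canonical from miRNA-like loci, and the published
non-canonical locus (4 criteria met, no hairpin, no star) fixes the split.
When evidence is absent, criterion 6 defaults to false, so validation must
then come from sequence-computable criteria. The classifier is monotone:
upgrading any criterion never demotes a locus (property-tested over all 64
criteria vectors).

## Synthetic data

The generator writes an i.i.d. genome at 23% GC (the study organism is
AT-rich), splices in hairpin loci (mature 20–24 nt, loop 4–15 nt, opposite
arm a reverse complement mutated to 85–100% identity, substitutions only),
and draws per-locus, per-strain read counts as Poisson with means
`wt_depth`, `wt_depth · fold_up` (suppressor; fold_up ~ U[5, 80]) and
`wt_depth / fold_down` (processing mutant; fold_down ~ U[5, 50]) — the fold
magnitudes span what the published table shows, from ~3-fold up to total
loss. Star reads are planted at the 2-nt-overhang duplex position at 10% of
mature abundance; 10% of mature reads get ±2 nt 5′-end jitter. miRNA-like
loci carry miRNA genetics via evidence overrides but a context rejected by
the hairpin call (redrawn until it fails) and no star reads. Suppressor-only
siRNA clusters and uniform background reads (15–35 nt) complete each
library to exactly `library_size` reads. An optional negative-binomial
dispersion switch exists but is off by default: Poisson is the minimal
model consistent with plain fold-change thresholds.

Defaults the study conditions leave open were fixed once: genome length
150 kb, `wt_depth_per_locus` 20, `library_size` 25 000 per strain, minimum
locus separation 400 nt — a desk-scale stand-in for a 34 Mb genome with a
few million reads, keeping background read density per nucleotide in a
realistic range. At these defaults with seed 42, discovery attains
sensitivity and precision ≥ 0.9 for canonical loci (asserted in
`tests/test_acceptance.py`).

What passing these tests shows: the criteria engine, fold/star geometry and
fold-change machinery are correct on data with exactly the assumed
structure. What it does not show: robustness to sequencing error, adapter
artifacts, expression-dependent biases, repeat families beyond simple
4-copy planting, or hairpins with insertion bulges — none of which the
generator emulates.

## Degenerate inputs and tie-breaks

Empty read files yield an empty candidate list, exit 0. A strain with
counted reads but zero aligned total is an internal-consistency error.
Windows extending past chromosome ends are clipped and logged. Cluster
modal-read ties resolve to the highest count, then leftmost placement;
mirror-pair ties to the plus strand, then leftmost. Candidates are reported
sorted by (chromosome, start), ids assigned after sorting, so output is
independent of read input order (tested).
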