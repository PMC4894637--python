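# mircall

miRNA discovery from three-strain small-RNA sequencing in *Dictyostelium
discoideum*-style genetic designs.

## The problem

In the social amoeba *D. discoideum*, the microprocessor (the Dicer-like
nuclease DrnB with the dsRNA-binding protein RbdB) excises miRNAs from
hairpin precursors, while the Argonaute AgnA suppresses their accumulation.
This creates a clean genetic contrast for discovering miRNAs from small-RNA
sequencing of three strains:

* **wild type** (AX2) — baseline expression,
* **processing mutant** (rbdB⁻) — genuine miRNAs are lost,
* **suppressor mutant** (agnA⁻) — genuine miRNAs rise several-fold.

`mircall` turns that contrast into a reusable pipeline: it places reads on
the genome by exact matching, seeds candidate loci from suppressor-strain
read clusters, quantifies each locus arm in ±5 nt windows, folds the locus
context, and applies six identification criteria:

1. mature length 20–24 nt;
2. ≥ 3-fold higher in the suppressor mutant than wild type;
3. ≥ 3-fold lower in the processing mutant than wild type;
4. the mature resides in a hairpin-like structure;
5. a corresponding star (miRNA-5p/-3p partner) sequence exists in the reads;
6. detectable by Northern blot (an experimental input, never computed).

A locus is **validated** when at least four criteria hold. Validated loci
with both hairpin and star (c4 ∧ c5) are **canonical miRNAs**; validated
loci without that pair are non-canonical **miRNA-like** RNAs — a class that
behaves like a miRNA genetically but lacks the fold-back precursor.

Expression is compared as reads per million aligned (RPM), with per-locus
fold changes taken as the maximum over the 5p/3p arms and the conventions
x/0 = +∞ (x > 0) and 0/0 = 0, so that a locus whose processing-mutant
signal vanishes entirely passes criterion 3. Secondary structure uses the
Nussinov maximum-pairing dynamic program (nested {AU, GC, GU} pairs,
minimum loop 3 nt) with a two-stage hairpin test and standard Dicer duplex
geometry (2-nt 3′ overhangs) for star prediction — see
[docs/methods.md](docs/methods.md).

## Worked example

The package bundles the published table of seven loci (13 sequenced arms)
with their per-strain relative expression. Replaying it through the
criteria engine:

```bash
$ mircall replay
locus_id        length  criteria        n_met   fold_up fold_down       class   known
ddi-miR-1176    21      1,2,3,4,5,6     6       83.82   inf     CANONICAL       yes
ddi-miR-1177    21      1,2,3,4,5,6     6       23.87   inf     CANONICAL       yes
miRNA_can_D1    22      1,2,3,4,5,6     6       10.90   inf     CANONICAL       no
miRNA_can_D2    22      1,2,3,4,5,6     6       inf     8.48    CANONICAL       no
ddi-mir-7097    21      1,2,3,4,5,6     6       59.09   5.34    CANONICAL       yes
miRNA_can_D3    21      1,2,3,4,5,6     6       7.86    20.61   CANONICAL       no
miRNA-like_D4   22      1,2 (based on NB),3 (based on NB),6     4       2.06    0.02    MIRNA_LIKE      no
# 4 newly identified validated species
```

Reading the output: `fold_up` is the suppressor/wild-type ratio and
`fold_down` the wild-type/processing-mutant ratio, each maximised over the
locus arms (`inf` marks a strain with zero signal). The three previously
unreported canonical loci clear both 3-fold bounds (minimum fold-up 7.86,
minimum fold-down 8.48), while the miRNA-like locus fails them from
sequencing (2.06-fold up) and is credited criteria 2 and 3 from blot
evidence — four criteria in total, validated, but non-canonical because it
has no hairpin and no star.

The full pipeline on synthetic data with known ground truth:

```bash
mircall simulate --out sim --seed 42
mircall discover --genome sim/genome.fa \
    --wt sim/reads_wt.fastq --proc sim/reads_proc_mutant.fastq \
    --supp sim/reads_supp_mutant.fastq --evidence sim/evidence.tsv \
    --out results
# 28 candidate loci, 25 validated; reports in results
```

`results/` then holds `candidates.gff3` (1-based), `candidates.bed`
(0-based), a `report.tsv` shaped like the worked example, and `run.log`.
At these defaults (20 planted canonical, 3 miRNA-like, 5 suppressor-only
siRNA loci) discovery recovers canonical loci with sensitivity and
precision ≥ 0.9 (`tests/test_acceptance.py` asserts this exact run).

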