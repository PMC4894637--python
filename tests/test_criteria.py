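"""Criteria evaluation, classification rules, seeding and discovery."""

import math

import pytest

from mircall.criteria import (
    Classification,
    CriteriaVector,
    CriterionSource,
    bundled_replay_table,
    classify_candidate,
    discover_mirnas,
    evaluate_candidate,
    replay_classification,
    seed_candidates,
)
from mircall.mapping import map_reads
from mircall.quantify import FoldChangeFlags
from mircall.seqio import EvidenceRecord, Strain, StrainLibrary
from mircall.synthetic_data import SimulationConfig, simulate_dataset


def _flags(c2=False, c3=False, up=1.0, down=1.0):
    return FoldChangeFlags("L", fold_up=up, fold_down=down, c2=c2, c3=c3)


class TestEvaluateCandidate:
    def test_fully_supported_known_mirna_meets_all_six(self):
        # the ddi-miR-1176 pattern: 21 nt, strong genetics, hairpin, star, blot
        cv = evaluate_candidate(
            mature_length=21,
            fold_flags=_flags(c2=True, c3=True, up=83.8, down=math.inf),
            hairpin_ok=True,
            star_supported=True,
            evidence=EvidenceRecord(northern=True),
        )
        assert cv.n_met == 6 and cv.met() == (1, 2, 3, 4, 5, 6)
        assert cv.criteria_string() == "1,2,3,4,5,6"

    def test_blot_override_reproduces_non_canonical_pattern(self):
        # the miRNA-like pattern: expression criteria fail from sequencing
        # (2.06-fold < 3) but blot evidence grants them; no hairpin, no star
        cv = evaluate_candidate(
            mature_length=22,
            fold_flags=_flags(c2=False, c3=False, up=2.06, down=0.016),
            hairpin_ok=False,
            star_supported=False,
            evidence=EvidenceRecord(northern=True, override_c2=True, override_c3=True),
        )
        assert cv.met() == (1, 2, 3, 6) and cv.n_met == 4
        assert cv.c2_source is CriterionSource.NB_OVERRIDE
        assert "(based on NB)" in cv.criteria_string()

    def test_override_never_fires_when_sequence_passes(self):
        cv = evaluate_candidate(
            21, _flags(c2=True, c3=True), True, True,
            EvidenceRecord(northern=True, override_c2=True, override_c3=True),
        )
        assert cv.c2_source is CriterionSource.SEQ

    def test_all_false_inputs(self):
        cv = evaluate_candidate(30, _flags(), False, False, None)
        assert cv.n_met == 0 and cv.criteria_string() == ""

    def test_c6_requires_positive_evidence(self):
        assert not evaluate_candidate(21, _flags(), False, False, None).c6
        assert not evaluate_candidate(
            21, _flags(), False, False, EvidenceRecord(northern=None)
        ).c6


class TestClassifyCandidate:
    @pytest.mark.parametrize("flags,expected", [
        (dict(c1=1, c2=1, c3=1, c4=1, c5=1, c6=1), Classification.CANONICAL),
        (dict(c1=1, c2=1, c3=1, c6=1), Classification.MIRNA_LIKE),
        (dict(c1=1, c2=1, c3=1), Classification.REJECTED),  # threshold boundary
        (dict(c1=1, c2=1, c4=1, c5=1), Classification.CANONICAL),
        (dict(c1=1, c2=1, c3=1, c4=1), Classification.MIRNA_LIKE),  # no star
    ])
    def test_validated_rule_and_canonical_split(self, flags, expected):
        cv = CriteriaVector(**{k: bool(v) for k, v in flags.items()})
        assert classify_candidate(cv) is expected

    def test_monotone_upgrading_criteria_never_demotes(self):
        rank = {
            Classification.REJECTED: 0,
            Classification.MIRNA_LIKE: 1,
            Classification.CANONICAL: 2,
        }
        names = ["c1", "c2", "c3", "c4", "c5", "c6"]
        for bits in range(64):
            base = CriteriaVector(**{
                n: bool(bits >> i & 1) for i, n in enumerate(names)
            })
            before = rank[classify_candidate(base)]
            for i, n in enumerate(names):
                if getattr(base, n):
                    continue
                upgraded = CriteriaVector(**{
                    m: bool(bits >> j & 1) or m == n
                    for j, m in enumerate(names)
                })
                assert rank[classify_candidate(upgraded)] >= before


@pytest.fixture(scope="module")
def results():
    return {r.locus_id: r for r in replay_classification(bundled_replay_table())}


class TestReplay:

    def test_reproduces_printed_criteria_sets_for_all_seven_loci(self, results):
        full = (1, 2, 3, 4, 5, 6)
        assert results["ddi-miR-1176"].criteria.met() == full
        assert results["ddi-miR-1177"].criteria.met() == full
        assert results["ddi-mir-7097"].criteria.met() == full
        assert results["miRNA_can_D1"].criteria.met() == full
        assert results["miRNA_can_D2"].criteria.met() == full
        assert results["miRNA_can_D3"].criteria.met() == full
        assert results["miRNA-like_D4"].criteria.met() == (1, 2, 3, 6)

    def test_known_and_new_species_split(self, results):
        known = {k for k, r in results.items() if r.known}
        assert known == {"ddi-miR-1176", "ddi-miR-1177", "ddi-mir-7097"}

    def test_classification_matches_published_table(self, results):
        for locus, r in results.items():
            expected = (
                Classification.MIRNA_LIKE if locus == "miRNA-like_D4"
                else Classification.CANONICAL
            )
            assert r.classification is expected, locus


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(SimulationConfig(
        genome_length=40_000, n_canonical=2, n_mirna_like=0,
        n_background_loci=0, library_size=3_000, seed=11,
    ))


class TestSeeding:
    def test_planted_loci_seed_at_planted_spans(self, small_dataset):
        ds = small_dataset
        placements = map_reads(ds.libraries, ds.genome)
        seeds = seed_candidates(placements)
        spans = {(s.window.start, s.window.end, s.window.strand) for s in seeds}
        for locus in ds.truth:
            assert (locus.mature_span[0], locus.mature_span[1], locus.strand) in spans

    def test_sparse_background_below_min_reads_seeds_nothing(self, small_dataset):
        ds = small_dataset
        placements = map_reads(ds.libraries, ds.genome)
        seeds = seed_candidates(placements, min_reads=10_000)
        assert seeds == []

    def test_distant_loci_never_merge(self, small_dataset):
        # planted loci are hundreds of nt apart: one seed each, never merged
        ds = small_dataset
        placements = map_reads(ds.libraries, ds.genome)
        seeds = seed_candidates(placements, max_cluster_gap=30)
        starts = sorted(s.window.start for s in seeds)
        assert len(starts) >= len(ds.truth)


class TestDiscover:
    def test_read_order_does_not_change_output(self, small_dataset):
        ds = small_dataset
        libs_rev = {
            s: StrainLibrary(s, list(reversed(lib.reads)))
            for s, lib in ds.libraries.items()
        }
        a = discover_mirnas(ds.genome, ds.libraries, ds.evidence)
        b = discover_mirnas(ds.genome, libs_rev, ds.evidence)
        assert [
            (c.locus_id, c.mature_window.start, c.classification) for c in a
        ] == [
            (c.locus_id, c.mature_window.start, c.classification) for c in b
        ]

    def test_output_sorted_by_position(self, small_dataset):
        ds = small_dataset
        candidates = discover_mirnas(ds.genome, ds.libraries, ds.evidence)
        keys = [(c.chrom_id, c.mature_window.start) for c in candidates]
        assert keys == sorted(keys)

    def test_empty_libraries_give_empty_candidate_list(self, small_dataset):
        empty = {s: StrainLibrary(s, []) for s in Strain}
        assert discover_mirnas(small_dataset.genome, empty) == []

    def test_missing_strain_is_config_error(self, small_dataset):
        libs = dict(small_dataset.libraries)
        del libs[Strain.PROC_MUTANT]
        with pytest.raises(ValueError, match="missing strain"):
            discover_mirnas(small_dataset.genome, libs)
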