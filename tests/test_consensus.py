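"""Replicate consensus, overlap percentages and chromatin-state logic."""

import numpy as np
import pytest

from cobindkit.consensus import (
    CHROMATIN_STATES,
    MissingMarkError,
    UndefinedPercentageError,
    build_consensus,
    define_chromatin_states,
    percent_overlap,
    state_cooccupancy,
)
from cobindkit.intervals import normalize, overlapping_subset

from conftest import allpairs_counts, as_triples, bitmap_of, intervals_from_bitmap, random_triples


class TestBuildConsensus:
    def test_single_replicate_identity(self):
        rep = normalize([("chr1", 0, 100)])
        assert as_triples(build_consensus([rep])) == [("chr1", 0, 100)]

    def test_common_region_of_three_replicates(self):
        reps = [
            normalize([("chr1", 0, 100)]),
            normalize([("chr1", 50, 150)]),
            normalize([("chr1", 90, 200)]),
        ]
        assert as_triples(build_consensus(reps)) == [("chr1", 90, 100)]

    def test_sliver_below_5bp_removed(self):
        reps = [normalize([("chr1", 0, 100)]), normalize([("chr1", 97, 150)])]
        assert len(build_consensus(reps)) == 0  # common region is 3 bp wide

    def test_exactly_5bp_kept(self):
        reps = [normalize([("chr1", 0, 100)]), normalize([("chr1", 95, 150)])]
        assert as_triples(build_consensus(reps)) == [("chr1", 95, 100)]

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_replicate_order_invariance_and_monotone_shrinkage(self):
        rng = np.random.default_rng(29)
        genome = {"chr1": 20_000}
        for _ in range(30):
            reps = [
                normalize(random_triples(rng, genome, n_max=25, w_max=600))
                for _ in range(3)
            ]
            forward = build_consensus(reps)
            shuffled = build_consensus([reps[2], reps[0], reps[1]])
            assert as_triples(forward) == as_triples(shuffled)
            # adding a replicate never enlarges coverage
            two = build_consensus(reps[:2], min_width=1)
            three = build_consensus(reps, min_width=1)
            assert three.total_width() <= two.total_width()


class TestPercentOverlap:
    def test_identical_sets_100(self):
        s = normalize([("chr1", 0, 100), ("chr1", 200, 300)])
        report = percent_overlap(s, s, "self")
        assert report.percent == 100.0
        assert report.n_overlapping_ctcf == report.n_consensus == 2

    def test_disjoint_zero(self):
        a = normalize([("chr1", 0, 100)])
        b = normalize([("chr2", 0, 100)])
        assert percent_overlap(a, b).percent == 0.0

    def test_empty_factor_undefined(self):
        with pytest.raises(UndefinedPercentageError):
            percent_overlap(normalize([]), normalize([("chr1", 0, 5)]))

    def test_percent_bounds_and_integer_counts(self):
        rng = np.random.default_rng(31)
        genome = {"chr1": 20_000}
        for _ in range(30):
            f = normalize(random_triples(rng, genome, n_max=25))
            c = normalize(random_triples(rng, genome, n_max=25))
            if len(f) == 0:
                continue
            report = percent_overlap(f, c)
            assert 0.0 <= report.percent <= 100.0
            assert report.n_overlapping_ctcf <= report.n_consensus
            assert isinstance(report.n_overlapping_ctcf, int)

    def test_rounding_only_at_report_time(self):
        f = normalize([("chr1", 0, 10), ("chr1", 100, 110), ("chr1", 200, 210)])
        c = normalize([("chr1", 5, 8)])
        report = percent_overlap(f, c)
        assert report.percent == pytest.approx(100.0 / 3.0)
        assert report.percent_rounded == 33


def _marks(**overrides):
    base = {
        "H3K4me3": normalize([("chr1", 0, 100)]),
        "H3K9me3": normalize([("chr1", 200, 300)]),
        "H3K27me3": normalize([("chr1", 400, 500)]),
        "H3K27ac": normalize([("chr1", 600, 700)]),
        "H3K4me1": normalize([("chr1", 650, 750)]),
        "H3K36me3": normalize([("chr1", 800, 900)]),
        "H3K79me2": normalize([("chr1", 850, 950)]),
    }
    base.update(overrides)
    return base


class TestChromatinStates:
    def test_composite_states_are_intersections(self):
        states = define_chromatin_states(
            _marks(
                H3K27ac=normalize([("chr1", 0, 50)]),
                H3K4me1=normalize([("chr1", 40, 90)]),
            )
        )
        assert as_triples(states["active_enhancer"]) == [("chr1", 40, 50)]

    def test_single_mark_states_pass_through(self):
        marks = _marks()
        states = define_chromatin_states(marks)
        assert as_triples(states["active_promoter"]) == as_triples(marks["H3K4me3"])
        assert as_triples(states["inactive_enhancer"]) == as_triples(marks["H3K9me3"])
        assert as_triples(states["inactive_promoter"]) == as_triples(marks["H3K27me3"])

    def test_disjoint_marks_give_empty_composites(self):
        states = define_chromatin_states(_marks())
        # fixture marks overlap within each composite pair; make them disjoint
        states = define_chromatin_states(
            _marks(
                H3K4me1=normalize([("chr2", 0, 50)]),
                H3K79me2=normalize([("chr2", 100, 150)]),
            )
        )
        assert len(states["active_enhancer"]) == 0
        assert len(states["gene_body"]) == 0
        assert len(states["active_promoter"]) == 1

    def test_missing_mark_named_in_error(self):
        marks = _marks()
        del marks["H3K79me2"]
        with pytest.raises(MissingMarkError, match="H3K79me2"):
            define_chromatin_states(marks)

    def test_composite_states_match_bitmap_oracle(self):
        rng = np.random.default_rng(37)
        genome = {"chr1": 20_000}
        for _ in range(20):
            raw = {m: random_triples(rng, genome, n_max=20) for m in _marks()}
            states = define_chromatin_states(
                {m: normalize(t) for m, t in raw.items()}
            )
            for state, state_marks in CHROMATIN_STATES.items():
                bits = bitmap_of(raw[state_marks[0]], genome)["chr1"]
                for mark in state_marks[1:]:
                    bits = bits & bitmap_of(raw[mark], genome)["chr1"]
                assert as_triples(states[state]) == intervals_from_bitmap(
                    {"chr1": bits}
                )


class TestStateCooccupancy:
    def test_peaks_inside_active_promoters_score_100(self):
        states = define_chromatin_states(_marks())
        peaks = normalize([("chr1", 10, 30), ("chr1", 50, 80)])
        result = state_cooccupancy(peaks, states)
        assert result["active_promoter"] == 100.0

    def test_all_states_empty_gives_zero(self):
        states = {name: normalize([]) for name in CHROMATIN_STATES}
        peaks = normalize([("chr1", 0, 100)])
        assert set(state_cooccupancy(peaks, states).values()) == {0.0}

    def test_empty_peaks_undefined(self):
        with pytest.raises(UndefinedPercentageError):
            state_cooccupancy(normalize([]), define_chromatin_states(_marks()))

    def test_counts_match_allpairs_oracle(self):
        rng = np.random.default_rng(41)
        genome = {"chr1": 20_000}
        for _ in range(20):
            peaks = normalize(random_triples(rng, genome, n_max=25))
            if len(peaks) == 0:
                continue
            raw = {m: random_triples(rng, genome, n_max=15) for m in _marks()}
            states = define_chromatin_states({m: normalize(t) for m, t in raw.items()})
            result = state_cooccupancy(peaks, states)
            for state, regions in states.items():
                counts = allpairs_counts(as_triples(peaks), as_triples(regions))
                expect = 100.0 * sum(1 for c in counts if c > 0) / len(peaks)
                assert result[state] == pytest.approx(expect)
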