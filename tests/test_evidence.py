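"""Evidence integration (procedure Step 5): candidate detection and classing."""

import numpy as np
import pytest

from remreg.core import CoordinateError, GenomicInterval
from remreg.ctcf_refine import Boundary, SearchRegion
from remreg.evidence import (EvidenceConfig, RegionClass, distance_to_gene,
                             find_candidates)
from remreg.fixtures import SimulationConfig, random_locus
from remreg.io_formats import FeatureTrack, ScoredFeature, TrackClass

CHROM = "chr18"
GENE = GenomicInterval.from_printed(2_645_885, 2_795_015, CHROM)


def _region(start=2_531_951, end=2_922_551):
    iv = GenomicInterval(CHROM, start, end)
    return SearchRegion(iv, Boundary("fragment_edge", start),
                        Boundary("fragment_edge", end))


class TestWorkedExample:
    def test_two_candidates_at_printed_positions(self, locus, prediction):
        spans = [c.interval.to_printed() for c in prediction.candidates]
        assert spans == [(2_561_489, 2_562_509), (2_631_527, 2_632_188)]

    def test_proximal_candidate_is_enhancer_like(self, prediction):
        distal, proximal = prediction.candidates
        assert proximal.region_class is RegionClass.ENHANCER_LIKE
        classes = proximal.evidence_classes()
        assert TrackClass.H3K4ME3 not in classes
        assert {TrackClass.ENHANCER, TrackClass.H3K27AC, TrackClass.H3K4ME1} <= classes

    def test_distal_candidate_is_promoter_like(self, prediction):
        distal, _ = prediction.candidates
        assert distal.region_class is RegionClass.PROMOTER_LIKE
        assert TrackClass.H3K4ME3 in distal.evidence_classes()
        assert any("promoter" in f.name.lower()
                   for f in distal.features_of(TrackClass.CHROMHMM))

    def test_distances_to_gene(self, prediction):
        distal, proximal = prediction.candidates
        assert proximal.distance_to_gene == -13_696   # ~14 kb upstream
        assert distal.distance_to_gene == -83_375     # ~84 kb upstream
        assert round(proximal.distance_to_gene / 1000, 1) == -13.7
        assert round(distal.distance_to_gene / 1000, 1) == -83.4

    def test_decoy_tfbs_without_marks_not_emitted(self, prediction):
        # a lone TFBS (ZNF143) inside the search region has no mark support
        for cand in prediction.candidates:
            assert "ZNF143" not in [f.name for _, f in cand.evidence]
        assert len(prediction.candidates) == 2


class TestFindCandidates:
    def test_no_tracks_is_an_error(self):
        with pytest.raises(ValueError):
            find_candidates(_region(), [])

    def test_wrong_chromosome_is_an_error(self):
        feat = ScoredFeature(GenomicInterval("chr7", 0, 100), "x", 10)
        with pytest.raises(CoordinateError):
            find_candidates(_region(), [FeatureTrack(TrackClass.TFBS, [feat])])

    def test_tracks_without_features_in_region_yield_nothing(self):
        tracks = [FeatureTrack(TrackClass.TFBS, []),
                  FeatureTrack(TrackClass.H3K27AC, [])]
        assert find_candidates(_region(), tracks) == []

    def test_anchorless_marks_yield_nothing(self):
        mark = ScoredFeature(GenomicInterval(CHROM, 2_600_000, 2_610_000),
                             "H3K27ac", 500)
        tracks = [FeatureTrack(TrackClass.TFBS, []),
                  FeatureTrack(TrackClass.H3K27AC, [mark])]
        assert find_candidates(_region(), tracks) == []

    def test_track_permutation_invariance(self, locus, prediction):
        rng = np.random.default_rng(5)
        tracks = [t for t in locus.tracks if t.track_class is not TrackClass.CTCF]
        for _ in range(5):
            shuffled = list(tracks)
            rng.shuffle(shuffled)
            cands = find_candidates(prediction.search_region, shuffled,
                                    EvidenceConfig(primary_cell_line="GM06990"),
                                    gene=GENE)
            assert [c.interval for c in cands] == \
                [c.interval for c in prediction.candidates]

    def test_candidates_are_non_nested_and_anchored(self, prediction):
        anchors = {TrackClass.TFBS, TrackClass.DNASE}
        ivs = [c.interval for c in prediction.candidates]
        for i, a in enumerate(ivs):
            assert prediction.candidates[i].evidence_classes() & anchors
            for j, b in enumerate(ivs):
                if i != j:
                    assert not a.contains(b)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_region_recovered_among_decoys(self, seed):
        from remreg import pipeline
        bundle = random_locus(SimulationConfig(seed=1000 + seed))
        res = pipeline.predict(bundle.gene, bundle.contacts_coarse, bundle.tracks)
        assert [c.interval for c in res.candidates] == [bundle.planted_region]


class TestDistance:
    def test_overlapping_candidate_has_zero_distance(self):
        from remreg.evidence import CandidateRegion
        cand = CandidateRegion(GenomicInterval(CHROM, 2_645_000, 2_646_000))
        assert distance_to_gene(cand, GENE) == 0

    def test_downstream_is_positive(self):
        from remreg.evidence import CandidateRegion
        cand = CandidateRegion(GenomicInterval(CHROM, 2_800_000, 2_801_000))
        assert distance_to_gene(cand, GENE) == 2_800_000 - 2_795_015

    def test_chromosome_mismatch_is_an_error(self):
        from remreg.evidence import CandidateRegion
        cand = CandidateRegion(GenomicInterval("chr4", 0, 10))
        with pytest.raises(CoordinateError):
            distance_to_gene(cand, GENE)
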