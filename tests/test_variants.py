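"""Variant annotation, cohort tallies and the methylation average."""

from fractions import Fraction

import numpy as np
import pytest

from remreg.core import GenomicInterval
from remreg.io_formats import (ConservationTrack, FeatureTrack, ScoredFeature,
                               TrackClass, Variant)
from remreg.variants import (MethylationProfile, annotate_variant,
                             cohort_summary, conservation_label,
                             mean_methylation)

CHROM = "chr18"


class TestAnnotateWorkedExample:
    def _annot(self, locus, prediction, pos):
        variant = next(v for v in locus.variants if v.pos == pos)
        tracks = locus.evidence_tracks()
        return annotate_variant(variant, prediction.candidates, tracks,
                                locus.known_variants, locus.conservation)

    def test_variant_2631886_inside_dhs_and_four_tfbs(self, locus, prediction):
        av = self._annot(locus, prediction, 2_631_886)
        assert [c.interval.to_printed() for c in av.containing_candidates] == \
            [(2_631_527, 2_632_188)]
        names = set(av.feature_names(TrackClass.TFBS))
        assert {"IRF1", "STAT1", "STAT2", "RUNX3"} <= names
        assert av.feature_names(TrackClass.DNASE) == ["DHS"]
        assert av.novel and av.conserved
        assert av.conservation_score == pytest.approx(0.431)

    def test_variant_2631610_in_stat1_but_not_irf1_or_dhs(self, locus, prediction):
        av = self._annot(locus, prediction, 2_631_610)
        names = set(av.feature_names(TrackClass.TFBS))
        assert "STAT1" in names and "IRF1" not in names
        assert av.feature_names(TrackClass.DNASE) == []
        assert av.containing_candidates[0].interval.to_printed() == \
            (2_631_527, 2_632_188)
        assert av.conservation_score == pytest.approx(0.557)

    def test_known_snp_not_novel(self, locus, prediction):
        av = self._annot(locus, prediction, 2_631_858)
        assert not av.novel
        assert av.conservation_score == pytest.approx(0.691)

    def test_distant_variant_has_no_annotations(self, locus, prediction):
        av = annotate_variant(Variant(CHROM, 1_000_000, "A", "G"),
                              prediction.candidates, locus.evidence_tracks())
        assert av.containing_candidates == []
        assert av.overlapping_features == []
        assert av.conservation_score is None and av.conserved is None


@pytest.mark.parametrize("seed", range(5))
def test_overlap_lists_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    feats = [ScoredFeature(GenomicInterval(CHROM, int(s), int(s) + int(l)),
                           f"f{i}", int(rng.integers(0, 1001)))
             for i, (s, l) in enumerate(zip(rng.integers(0, 100_000, 150),
                                            rng.integers(1, 2_000, 150)))]
    track = FeatureTrack(TrackClass.TFBS, feats)
    for pos in rng.integers(1, 100_000, 200):
        v = Variant(CHROM, int(pos), "A", "C")
        av = annotate_variant(v, [], [track])
        got = [f for _, f in av.overlapping_features]
        brute = [f for f in feats
                 if f.interval.start < pos <= f.interval.end]
        assert got == brute


class TestConservation:
    @pytest.mark.parametrize("score,expected", [
        (0.557, True), (0.431, True), (0.691, True), (-1.2, False), (0.0, False),
    ])
    def test_phylop_sign_semantics(self, score, expected):
        assert conservation_label(score) is expected

    def test_configurable_threshold(self):
        assert conservation_label(0.431, threshold=0.5) is False


class TestCohort:
    def test_printed_cohort_proportions(self):
        summary = cohort_summary(2_631_858, ["C"] * 182 + ["T"] * 47)
        assert summary.allele_counts == {"C": 182, "T": 47}
        assert summary.n == 229
        assert summary.frequencies["C"] == Fraction(182, 229)
        assert sum(summary.frequencies.values()) == 1

    def test_uniform_cohort(self):
        summary = cohort_summary(1, ["A"] * 7)
        assert summary.frequencies == {"A": Fraction(1)}

    def test_hand_count(self):
        summary = cohort_summary(5, ["A", "A", "G"])
        assert summary.allele_counts == {"A": 2, "G": 1}

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            cohort_summary(1, [])


class TestMethylation:
    def test_constant_ratios(self):
        assert mean_methylation(MethylationProfile([0.24] * 10)) == 24

    def test_hand_mean(self):
        assert mean_methylation(MethylationProfile([0] * 5 + [1] * 5)) == 50

    def test_wrong_site_count_is_an_error(self):
        with pytest.raises(ValueError):
            MethylationProfile([0.2] * 9)

    def test_out_of_range_ratio_is_an_error(self):
        with pytest.raises(ValueError):
            MethylationProfile([0.2] * 9 + [1.4])

    def test_site_order_invariance(self):
        rng = np.random.default_rng(11)
        ratios = list(rng.uniform(0, 1, 10))
        base = mean_methylation(MethylationProfile(ratios))
        for _ in range(10):
            rng.shuffle(ratios)
            assert mean_methylation(MethylationProfile(list(ratios))) == base
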