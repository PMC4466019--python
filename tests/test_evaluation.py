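"""Overlap statistics, apex shifts, annotation, recovery, lost peaks."""

import math

import numpy as np
import pytest

from chipplex.evaluate import (
    annotate_peaks,
    apex_shift_distribution,
    gene_recovery,
    interval_recovery,
    lost_peak_characteristics,
    pairwise_overlap_matrix,
    percent_overlap,
)
from chipplex.model import AnnotationParams, GeneModel, Peak


def mk(chrom, start, end, apex=None, p=1e-20, fold=4.0):
    return Peak(chrom, start, end, start if apex is None else apex, p, fold)


def intervals_overlap(a, b):
    """Oracle: [a0,a1) and [b0,b1) share >= 1 base."""
    return a[0] < b[1] and b[0] < a[1]


class TestPercentOverlap:
    def test_single_base_overlap_counts(self):
        r = percent_overlap([mk("chr1", 100, 200)], [mk("chr1", 199, 300)])
        assert r.percent_overlap_of_x == 100.0

    def test_half_open_abutment_does_not(self):
        r = percent_overlap([mk("chr1", 100, 200)], [mk("chr1", 200, 300)])
        assert r.percent_overlap_of_x == 0.0

    def test_self_overlap_is_total(self):
        x = [mk("chr1", 10, 50), mk("chr1", 100, 120), mk("chr2", 5, 500)]
        assert percent_overlap(x, x).percent_overlap_of_x == 100.0

    def test_two_of_three(self):
        x = [mk("chr1", 0, 100), mk("chr1", 200, 300), mk("chr1", 400, 500)]
        y = [mk("chr1", 50, 250)]
        r = percent_overlap(x, y)
        assert r.n_x_overlapping == 2
        assert r.percent_overlap_of_x == pytest.approx(66.7, abs=0.05)

    def test_empty_x_is_nan(self):
        assert math.isnan(percent_overlap([], [mk("chr1", 0, 10)]).percent_overlap_of_x)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            percent_overlap([mk("chr1", 100, 200), mk("chr1", 0, 50)], [])

    def test_matches_quadratic_oracle_on_random_sets(self):
        """Sweep implementation vs all-pairs check on random disjoint sets."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            sets = []
            for _set in range(2):
                n = rng.integers(1, 30)
                widths = rng.integers(1, 40, size=n)
                gaps = rng.integers(1, 50, size=n)
                # gaps between consecutive intervals keep each set disjoint
                starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths[:-1])])
                sets.append(
                    [mk("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)]
                )
            x, y = sets
            want = sum(
                any(intervals_overlap((a.start, a.end), (b.start, b.end)) for b in y)
                for a in x
            )
            assert percent_overlap(x, y).n_x_overlapping == want


class TestPairwiseMatrix:
    def test_identical_sets_all_100(self):
        x = [mk("chr1", 0, 10)]
        m = pairwise_overlap_matrix({"a": x, "b": list(x)})
        assert (m.values == 100.0).all()

    def test_disjoint_sets_off_diagonal_zero(self):
        m = pairwise_overlap_matrix(
            {"a": [mk("chr1", 0, 10)], "b": [mk("chr1", 20, 30)]}
        )
        assert m.loc["a", "b"] == 0.0 and m.loc["a", "a"] == 100.0

    def test_asymmetry_is_allowed(self):
        a = [mk("chr1", 0, 100), mk("chr1", 200, 300)]
        b = [mk("chr1", 50, 250)]
        m = pairwise_overlap_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == 100.0 and m.loc["b", "a"] == 100.0
        m2 = pairwise_overlap_matrix({"a": a, "c": [mk("chr1", 90, 110)]})
        assert m2.loc["a", "c"] == 50.0 and m2.loc["c", "a"] == 100.0


class TestApexShift:
    def test_identical_sets_shift_zero(self):
        x = [mk("chr1", 0, 1000, apex=400), mk("chr1", 2000, 2500, apex=2100)]
        res = apex_shift_distribution(x, x)
        assert np.all(res.shifts == 0) and res.fraction_within == 1.0

    def test_single_pair_signed_shift(self):
        ref = [mk("chr1", 0, 1000, apex=400)]
        query = [mk("chr1", 100, 900, apex=430)]
        res = apex_shift_distribution(ref, query)
        assert list(res.shifts) == [30]

    def test_no_overlap_gives_undefined_fraction(self):
        res = apex_shift_distribution([mk("chr1", 0, 100)], [mk("chr1", 500, 600)])
        assert res.n_matched == 0 and res.fraction_within is None

    def test_default_threshold_is_reference_median_width(self):
        ref = [mk("chr1", 0, 100), mk("chr1", 200, 500), mk("chr1", 600, 1100)]
        res = apex_shift_distribution(ref, ref)
        assert res.threshold == 300.0

    def test_matches_peak_of_maximal_overlap(self):
        ref = [mk("chr1", 0, 100, apex=10), mk("chr1", 100, 400, apex=300)]
        query = [mk("chr1", 50, 350, apex=200)]  # 50 bp vs 250 bp overlap
        res = apex_shift_distribution(ref, query, threshold=1000)
        assert list(res.shifts) == [200 - 300]


GENES = [
    GeneModel("gA", "chr1", "+", 2000, 7999),
    GeneModel("gB", "chr1", "-", 20_000, 12_000),
]


class TestAnnotate:
    def test_flank_boundary_inclusive(self):
        # window [1000, 3000] around TSS 2000 touches peak [900, 1100)
        ann, gene_set = annotate_peaks([mk("chr1", 900, 1100)], GENES)
        assert gene_set == {"gA"}

    def test_gap_of_100_not_assigned(self):
        ann, gene_set = annotate_peaks([mk("chr1", 0, 900)], GENES)
        assert gene_set == set()

    def test_tes_assignment_counts(self):
        # peak around gA's TES (7999) only
        ann, gene_set = annotate_peaks([mk("chr1", 8500, 8700)], GENES)
        assert gene_set == {"gA"}

    def test_peak_may_annotate_multiple_genes_once_each(self):
        close = [
            GeneModel("g1", "chr1", "+", 1000, 5000),
            GeneModel("g2", "chr1", "+", 1500, 5000),
        ]
        ann, gene_set = annotate_peaks([mk("chr1", 900, 1600)] * 1, close)
        assert gene_set == {"g1", "g2"}

    def test_matches_direct_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        flank = 1000
        for _ in range(200):
            genes = []
            for i in range(rng.integers(1, 15)):
                tss = int(rng.integers(0, 100_000))
                span = int(rng.integers(2000, 20_000))
                if rng.random() < 0.5:
                    genes.append(GeneModel(f"g{i}", "chr1", "+", tss, tss + span))
                else:
                    genes.append(GeneModel(f"g{i}", "chr1", "-", tss + span, tss))
            starts = np.cumsum(rng.integers(50, 4000, size=rng.integers(1, 15)))
            peaks = [mk("chr1", int(s), int(s + rng.integers(100, 2000))) for s in starts]
            _, got = annotate_peaks(peaks, genes, AnnotationParams(flank=flank))
            want = set()
            for g in genes:
                for p in peaks:
                    for site in (g.tss, g.tes):
                        lo, hi = max(0, site - flank), site + flank
                        if p.start <= hi and lo <= p.end - 1:  # closed-interval rule
                            want.add(g.gene_id)
            assert got == want


class TestGeneRecovery:
    def test_identity(self):
        assert gene_recovery({"a", "b"}, {"a", "b"}) == 100.0

    def test_nine_of_ten(self):
        ref = {f"g{i}" for i in range(10)}
        assert gene_recovery(ref, ref - {"g3"}) == 90.0

    def test_superset_query_is_total(self):
        a = {"x", "y"}
        b = {"z"}
        assert gene_recovery(a, a | b) == 100.0

    def test_asymmetric_denominator(self):
        assert gene_recovery({"a"}, {"a", "b"}) == 100.0
        assert gene_recovery({"a", "b"}, {"a"}) == 50.0

    def test_empty_reference_is_undefined(self):
        assert gene_recovery(set(), {"a"}) is None


class TestLostPeaks:
    def _annotation(self):
        # four genes with best peaks of increasing significance
        ann = {
            f"g{i}": [mk("chr1", i * 1000, i * 1000 + 100 * (i + 1), p=10.0 ** (-20 * (i + 1)))]
            for i in range(4)
        }
        return ann

    def test_no_loss_gives_empty_report(self):
        ann = self._annotation()
        rep = lost_peak_characteristics(ann, set(ann))
        assert rep.table.empty and rep.lost_genes == set()

    def test_lost_is_subset_of_reference(self):
        ann = self._annotation()
        rep = lost_peak_characteristics(ann, {"g0", "g2", "not_a_ref_gene"})
        assert rep.lost_genes <= set(ann)
        assert rep.lost_genes == {"g1", "g3"}

    def test_quartile_placement(self):
        ann = self._annotation()
        rep = lost_peak_characteristics(ann, {"g1", "g2", "g3"})  # lose weakest g0
        row = rep.table.iloc[0]
        assert row["gene_id"] == "g0"
        assert row["p_quartile"] == 4  # least significant quartile
        assert row["width_quartile"] == 1  # narrowest quartile

    def test_interval_recovery_tolerates_overlapping_truth(self):
        regions = [("chr1", 0, 500), ("chr1", 400, 900), ("chr2", 0, 100)]
        peaks = [mk("chr1", 450, 470)]
        assert interval_recovery(regions, peaks) == pytest.approx(100 * 2 / 3)
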