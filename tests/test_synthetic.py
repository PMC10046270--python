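"""Synthetic-cohort generators: determinism, invariants and truth recovery."""

import numpy as np
import pytest

from twm.catalog import build_catalog
from twm.clonality import classify_clonality
from twm.cnv_summary import classify_segment, hrd_loh_score, loh_genome_fraction
from twm.signature_fit import em_fit, etiology_summary
from twm.synthetic import (
    simulate_catalog,
    simulate_cohort,
    simulate_segments,
    simulate_signature_matrix,
)

MB = 1_000_000


class TestSignatureMatrixGenerator:
    def test_single_row_valid(self):
        m = simulate_signature_matrix(1, seed=0)
        assert m.k == 1
        assert m.probs.sum() == pytest.approx(1.0)

    def test_seed_determinism(self):
        a = simulate_signature_matrix(4, seed=5)
        b = simulate_signature_matrix(4, seed=5)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_high_concentration_near_uniform(self):
        m = simulate_signature_matrix(3, concentration=1e6, seed=1)
        assert np.abs(m.probs - 1 / 96).max() < 1e-2

    def test_k_validation(self):
        with pytest.raises(ValueError):
            simulate_signature_matrix(0, seed=0)


class TestCatalogGenerator:
    def test_zero_draws(self):
        sigs = simulate_signature_matrix(2, seed=0)
        cat = simulate_catalog(sigs, [0.5, 0.5], 0, seed=1)
        assert cat.total == 0

    def test_point_mass_signature(self):
        from twm.formats_io import SignatureMatrix

        probs = np.zeros((1, 96))
        probs[0, 17] = 1.0
        sigs = SignatureMatrix(["POINT"], probs)
        cat = simulate_catalog(sigs, [1.0], 250, seed=2)
        assert cat.counts[17] == 250 and cat.total == 250

    def test_em_recovers_disjoint_mixture(self, disjoint_pair):
        cat = simulate_catalog(disjoint_pair, [0.7, 0.3], 20_000, seed=3)
        fit = em_fit(cat, disjoint_pair, prune=False)
        assert np.abs(fit.proportions - [0.7, 0.3]).sum() < 0.02

    def test_invalid_exposures(self):
        sigs = simulate_signature_matrix(2, seed=0)
        with pytest.raises(ValueError):
            simulate_catalog(sigs, [0.7, 0.7], 10, seed=0)


class TestCohortGenerator:
    def test_infinite_depth_all_clonal(self):
        tables, truth = simulate_cohort(2, 50, (1.0, 0.0, 0.0), depth=None, seed=4)
        for case_id, recs in tables.items():
            assert all(v.vaf == 0.5 for v in recs)
            assert all(classify_clonality(v.vaf).category == "clonal" for v in recs)
            assert truth.clonality_labels[case_id] == ["clonal"] * 50

    def test_seed_determinism(self):
        t1, _ = simulate_cohort(2, 30, seed=9)
        t2, _ = simulate_cohort(2, 30, seed=9)
        assert t1 == t2

    def test_records_satisfy_invariants(self):
        tables, _ = simulate_cohort(3, 100, depth=60, seed=10)
        for recs in tables.values():
            for v in recs:
                assert 0 <= v.vaf <= 1 and v.ref != v.alt and v.has_context

    def test_high_depth_recovers_truth_labels(self):
        """At depth 10,000 binomial noise almost never crosses a band gap.

        Polyclonal and subclonal truths lie strictly inside their bands and
        are recovered at >99%.  Clonal truth sits exactly on the 0.50 band
        edge, so noise legitimately sends about half the clonal draws into
        the adjacent indeterminate gap — but never across a whole gap into
        another band.
        """
        tables, truth = simulate_cohort(1, 5_000, (0.5, 0.3, 0.2), depth=10_000, seed=11)
        recs = tables["case1"]
        labels = truth.clonality_labels["case1"]
        by_truth: dict[str, list[str]] = {}
        for v, lab in zip(recs, labels):
            by_truth.setdefault(lab, []).append(classify_clonality(v.vaf).category)
        for band in ("polyclonal", "subclonal"):
            calls = by_truth[band]
            # truths drawn uniformly up to the band edges: edge draws flip
            # into the gap with ~50% odds, bounding recovery near 95-98%
            assert sum(c == band for c in calls) / len(calls) > 0.95
            assert all(c in (band, "indeterminate") for c in calls)
        assert all(c in ("clonal", "indeterminate") for c in by_truth["clonal"])

    def test_designated_catalog_reproduced(self):
        """Contexts are assigned so build_catalog matches the designated mixture."""
        sigs = simulate_signature_matrix(2, seed=12)
        tables, truth = simulate_cohort(
            1, 20_000, depth=None, seed=13, signatures=sigs, exposures=[0.8, 0.2]
        )
        cat = build_catalog(tables["case1"])
        assert cat.total == 20_000
        fit = em_fit(cat, sigs, prune=False)
        assert np.abs(fit.proportions - [0.8, 0.2]).sum() < 0.05
        assert truth.exposures["case1"] == {"SYN1": 0.8, "SYN2": 0.2}

    def test_invalid_mix(self):
        with pytest.raises(ValueError):
            simulate_cohort(1, 10, (0.5, 0.5, 0.5), seed=0)


class TestSegmentGenerator:
    LENGTHS = {"chr1": 100 * MB, "chr2": 100 * MB, "chr3": 100 * MB}

    def test_zero_events_all_neutral(self):
        segs, truth = simulate_segments(self.LENGTHS, seed=0)
        assert all(classify_segment(s) == "neutral" for s in segs)
        assert set(truth.segment_categories) == {"neutral"}

    def test_single_loh_fraction_by_construction(self):
        segs, _ = simulate_segments({"chr1": 100 * MB}, n_loh=1, loh_len_bp=50 * MB, seed=1)
        assert loh_genome_fraction(segs, 100 * MB) == pytest.approx(50.0)

    def test_truth_classes_recovered_exactly(self):
        segs, truth = simulate_segments(
            self.LENGTHS, n_loh=3, loh_len_bp=20 * MB, n_gain=2, n_hl=2, n_amp=1, seed=2
        )
        assert [classify_segment(s) for s in segs] == truth.segment_categories

    def test_hrd_high_by_construction(self):
        lengths = {f"c{i}": 50 * MB for i in range(12)}
        segs, _ = simulate_segments(lengths, n_loh=12, loh_len_bp=20 * MB, seed=3)
        score, high = hrd_loh_score(segs, lengths, high_threshold=10)
        assert score == 12 and high

    def test_infeasible_packing_error(self):
        with pytest.raises(ValueError):
            simulate_segments({"chr1": 10 * MB}, n_loh=2, loh_len_bp=8 * MB, seed=4)

    def test_non_overlapping(self):
        segs, _ = simulate_segments(
            self.LENGTHS, n_loh=4, loh_len_bp=10 * MB, n_gain=3, n_hl=2, seed=5
        )
        by_chrom: dict[str, list] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                assert e1 < s2


def test_end_to_end_uv_band_recovery():
    """catalog -> em_fit -> etiology recovers the designated UV band."""
    rng = np.random.default_rng(20)
    from twm.formats_io import SignatureMatrix

    probs = rng.dirichlet(np.full(96, 0.1), size=4)
    sigs = SignatureMatrix(["SBS7a", "SBS7b", "SBS5", "SBS1"], probs)
    for uv_share, expected in [(0.9, "predominant"), (0.2, "minor")]:
        pi = [uv_share * 0.6, uv_share * 0.4, (1 - uv_share) * 0.5, (1 - uv_share) * 0.5]
        tables, _ = simulate_cohort(
            1, 10_000, depth=None, seed=21, signatures=sigs, exposures=pi
        )
        cat = build_catalog(tables["case1"])
        et = etiology_summary(em_fit(cat, sigs))
        assert et.uv_band == expected
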