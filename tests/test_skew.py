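"""GC-skew profiles, cumulative inflection, weighted termination, dif."""

import numpy as np
import pytest

from tertrap.genome import CircularGenome, GenomeError, reverse_complement
from tertrap.motif import load_dif_consensus
from tertrap.simulate import GenomeSpec, make_replichore_genome
from tertrap.skew import (
    TerActivity,
    cumulative_skew,
    expected_termination_position,
    gc_skew_profile,
    locate_dif,
    skew_extrema,
)

from .conftest import random_genome


class TestWindowedSkew:
    def test_all_g_window_is_plus_one(self):
        g = CircularGenome("g", "G" * 1000)
        p = gc_skew_profile(g, window=100)
        assert np.allclose(p.values, 1.0)

    def test_balanced_window_is_zero(self):
        g = CircularGenome("g", "GC" * 500)
        p = gc_skew_profile(g, window=100)
        assert np.allclose(p.values, 0.0)

    def test_no_gc_window_is_zero_by_convention(self):
        g = CircularGenome("g", "AT" * 500)
        p = gc_skew_profile(g, window=100)
        assert np.allclose(p.values, 0.0)

    def test_values_bounded(self):
        g = random_genome(20_000, seed=5, gc_bias=0.1)
        p = gc_skew_profile(g, window=500)
        assert np.all(p.values >= -1.0) and np.all(p.values <= 1.0)

    def test_reverse_complement_negates_values(self):
        g = random_genome(10_000, seed=6, gc_bias=0.08)
        w = 1000
        p = gc_skew_profile(g, window=w)
        m = gc_skew_profile(
            CircularGenome(g.id, reverse_complement(g.sequence)), window=w
        )
        # window starting at i maps to the mirrored window ending at L-i
        assert np.allclose(np.sort(m.values), np.sort(-p.values))

    def test_window_larger_than_genome_rejected(self):
        g = random_genome(100, seed=7)
        with pytest.raises(GenomeError):
            gc_skew_profile(g, window=101)


class TestCumulative:
    def test_constant_skew_gives_linear_ramp(self):
        g = CircularGenome("g", "G" * 5000)
        p = cumulative_skew(gc_skew_profile(g, window=500))
        assert np.allclose(p.cumulative, np.arange(1, 11) * 1.0)

    def test_two_replichore_genome_gives_tent(self):
        spec = GenomeSpec(L=200_000, oriC=1, terminus=100_001,
                          skew_delta=0.1, seed=11)
        g, _ = make_replichore_genome(spec)
        p = cumulative_skew(gc_skew_profile(g, window=1000))
        peak = int(np.argmax(p.cumulative))
        # tent apex at the terminus (window index ~100)
        assert abs(peak - 100) <= 2
        # rising then falling, approximately linear in both halves
        rising = np.diff(p.cumulative[: peak - 2])
        falling = np.diff(p.cumulative[peak + 2 :])
        assert rising.mean() > 0 and falling.mean() < 0

    def test_total_equals_last_cumulative(self):
        g = random_genome(10_000, seed=12, gc_bias=0.05)
        p = cumulative_skew(gc_skew_profile(g, window=500))
        assert p.cumulative[-1] == pytest.approx(p.values.sum())

    def test_overlapping_tiling_rejected(self):
        g = random_genome(10_000, seed=13)
        p = gc_skew_profile(g, window=1000, step=500)
        with pytest.raises(GenomeError):
            cumulative_skew(p)


class TestExtrema:
    def test_recovers_planted_terminus(self):
        spec = GenomeSpec(L=2_000_000, oriC=100_000, terminus=1_850_000,
                          skew_delta=0.04, seed=21)
        g, truth = make_replichore_genome(spec)
        p = cumulative_skew(gc_skew_profile(g, window=1000))
        ori, term = skew_extrema(p)
        assert abs(term - truth.terminus) <= 2000
        assert abs(ori - truth.oriC) <= 2000

    def test_rotation_shifts_estimates(self):
        spec = GenomeSpec(L=400_000, oriC=50_000, terminus=250_000,
                          skew_delta=0.08, seed=22)
        g, truth = make_replichore_genome(spec)
        w = 1000
        ori0, term0 = skew_extrema(cumulative_skew(gc_skew_profile(g, w)))
        k = 120_000  # multiple of the window so centers stay aligned
        ori1, term1 = skew_extrema(cumulative_skew(gc_skew_profile(g.rotated(k), w)))
        L = g.length
        assert (term1 - 1 + k) % L + 1 == pytest.approx(term0, abs=w)
        assert (ori1 - 1 + k) % L + 1 == pytest.approx(ori0, abs=w)

    def test_flat_genome_flagged(self):
        spec = GenomeSpec(L=100_000, oriC=1, terminus=50_000,
                          skew_delta=0.0, seed=23)
        g, _ = make_replichore_genome(spec)
        p = cumulative_skew(gc_skew_profile(g, window=1000))
        # delta = 0: the cumulative curve is noise; a truly flat curve is
        # only reached in expectation, so force the degenerate input
        p.cumulative = np.zeros_like(p.cumulative)
        ori, term = skew_extrema(p)
        assert ori is None and term is None and p.flat

    def test_origin_terminus_antipodal_on_symmetric_genome(self):
        spec = GenomeSpec(L=1_000_000, oriC=1, terminus=500_001,
                          skew_delta=0.06, seed=24)
        g, _ = make_replichore_genome(spec)
        w = 1000
        ori, term = skew_extrema(cumulative_skew(gc_skew_profile(g, w)))
        from tertrap.genome import circular_distance

        assert abs(circular_distance(ori, term, g.length) - 500_000) <= 2 * w

    def test_terminus_recovery_rate_19_of_20(self):
        """Across 20 seeded 2-Mb genomes the inflection lands within 2 kb of
        the planted terminus in at least 19."""
        hits = 0
        for seed in range(20):
            spec = GenomeSpec(L=2_000_000, oriC=1, terminus=1_000_000,
                              skew_delta=0.04, seed=seed)
            g, truth = make_replichore_genome(spec)
            _, term = skew_extrema(cumulative_skew(gc_skew_profile(g, 1000)))
            if abs(term - truth.terminus) <= 2000:
                hits += 1
        assert hits >= 19


class TestExpectedTermination:
    def test_single_site_returns_its_position(self):
        assert expected_termination_position(
            [TerActivity(123_456, 0.7)], 1_000_000
        ) == 123_456

    def test_equal_weights_give_midpoint(self):
        pos = expected_termination_position(
            [TerActivity(100_000, 1.0), TerActivity(200_000, 1.0)], 1_000_000
        )
        assert pos == 150_000

    def test_published_activity_weights(self):
        # sites at 100/200/300 kb with the measured TerA/B/C activities
        acts = [TerActivity(100_000, 0.19), TerActivity(200_000, 0.14),
                TerActivity(300_000, 0.85)]
        expected = (0.19 * 100_000 + 0.14 * 200_000 + 0.85 * 300_000) / 1.18
        pos = expected_termination_position(acts, 4_000_000)
        assert pos == int(round(expected))

    def test_rotation_and_weight_scale_invariance(self):
        L = 500_000
        acts = [TerActivity(480_000, 0.19), TerActivity(20_000, 0.85)]
        base = expected_termination_position(acts, L)
        k = 123_000
        rotated = [TerActivity((a.position - 1 + k) % L + 1, a.activity * 50)
                   for a in acts]
        moved = expected_termination_position(rotated, L)
        assert (moved - 1 - k) % L + 1 == base

    def test_wraps_origin_correctly(self):
        L = 1_000_000
        acts = [TerActivity(990_000, 1.0), TerActivity(10_000, 1.0)]
        assert expected_termination_position(acts, L) == 1_000_000

    def test_sites_spanning_more_than_half_rejected(self):
        with pytest.raises(GenomeError):
            expected_termination_position(
                [TerActivity(1, 1.0), TerActivity(400_000, 1.0),
                 TerActivity(800_000, 1.0)], 1_000_000
            )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(GenomeError):
            expected_termination_position([TerActivity(10, 0.0)], 100)


class TestLocateDif:
    def test_exact_planted_motif_found(self):
        spec = GenomeSpec(L=300_000, oriC=1, terminus=150_000,
                          skew_delta=0.03, dif=148_000, seed=31)
        g, truth = make_replichore_genome(spec)
        hit = locate_dif(g, load_dif_consensus(), max_mismatch=3)
        assert hit is not None
        assert hit.position == truth.dif
        assert hit.mismatches == 0

    def test_mutated_motif_found_within_budget(self):
        spec = GenomeSpec(L=100_000, oriC=1, terminus=50_000,
                          skew_delta=0.0, dif=40_000, seed=32)
        g, truth = make_replichore_genome(spec)
        motif = load_dif_consensus()
        mutated = "TT" + motif[2:]  # 2 mismatches vs planted copy
        hit = locate_dif(g, mutated, max_mismatch=3)
        assert hit is not None and hit.position == truth.dif
        assert hit.mismatches == 2

    def test_zero_budget_without_exact_match_is_none(self):
        g = random_genome(50_000, seed=33)
        assert locate_dif(g, load_dif_consensus(), max_mismatch=0) is None
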