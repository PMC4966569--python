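"""Border-aligned aggregation, smoothing, symmetrization and heat maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_catalog
from niebtools.profiles import (SIDE_FIVE, SIDE_THREE, BorderAlignedProfile,
                                aggregate, border_offsets, build_heatmap,
                                polynucleotide_coverage, polynucleotide_profile,
                                smooth, symmetrize, tag_heatmap, tss_profile)
from niebtools.core import GenomeSequence, TagTrack


class TestBorderOffsets:
    def test_inside_and_flank_conventions(self):
        # one barrier [10, 16) on a 30-bp chromosome
        off, side = border_offsets(np.array([10]), np.array([16]), 30, 5)
        # first base inside each border is offset -1; ties go to the 5' side
        assert off[10] == -1 and side[10] == SIDE_FIVE
        assert off[12] == -3 and side[12] == SIDE_FIVE   # width 6: 3 left, 3 right
        assert off[13] == -3 and side[13] == SIDE_THREE
        assert off[15] == -1 and side[15] == SIDE_THREE
        # flanks count outward from the border
        assert off[9] == 1 and side[9] == SIDE_FIVE
        assert off[16] == 1 and side[16] == SIDE_THREE
        assert off[20] == 5
        assert off[21] == 0   # beyond max_offset

    def test_gap_split_between_barriers(self):
        off, side = border_offsets(np.array([0, 20]), np.array([10, 30]), 30, 100)
        # 10-bp gap: first 5 to the 3' border of barrier 1, rest to the 5'
        assert off[10] == 1 and side[10] == SIDE_THREE
        assert off[14] == 5 and side[14] == SIDE_THREE
        assert off[15] == 5 and side[15] == SIDE_FIVE
        assert off[19] == 1 and side[19] == SIDE_FIVE

    def test_no_barriers(self):
        off, side = border_offsets(np.array([]), np.array([]), 50, 10)
        assert (off == 0).all()


class TestAggregate:
    def test_uniform_track_normalizes_to_one(self, small_catalog):
        values = {"chr1": np.ones(6000), "chr2": np.ones(2000)}
        prof = aggregate(values, small_catalog, 200, normalize=True)
        got = prof.mean[prof.count > 0]
        assert np.allclose(got, 1.0)

    def test_separation_inside_vs_flank(self, small_catalog):
        values = {"chr1": np.zeros(6000), "chr2": np.zeros(2000)}
        for chrom in ("chr1", "chr2"):
            starts, ends = small_catalog.intervals.per_chrom(chrom)
            for s, e in zip(starts, ends):
                values[chrom][s:e] = 1.0
        prof = aggregate(values, small_catalog, 100)
        inside = prof.mean[prof.offsets < 0]
        outside = prof.mean[prof.offsets > 0]
        assert np.nanmin(inside) == 1.0
        assert np.nanmax(outside) == 0.0

    def test_mass_conservation(self, small_catalog, rng):
        values = {"chr1": rng.random(6000), "chr2": rng.random(2000)}
        # with a huge max_offset every site contributes exactly once
        prof = aggregate(values, small_catalog, 10_000)
        total = sum(v.sum() for v in values.values())
        assert np.nansum(np.nan_to_num(prof.mean) * prof.count) == pytest.approx(total)

    def test_zero_genome_average_errors(self, small_catalog):
        values = {"chr1": np.zeros(6000)}
        with pytest.raises(ValueError, match="normalize"):
            aggregate(values, small_catalog, 100, normalize=True)

    def test_gc_dip_matches_generator_targets(self):
        from niebtools.simulate import SyntheticTruth, generate_genomes
        truth = SyntheticTruth()
        genome, catalog = generate_genomes(truth, {"chr1": 2_000_000}, seed=3)
        gc = {c: g.gc_indicator() for c, g in genome.items()}
        prof = aggregate(gc, catalog, 300)
        # interior offsets beyond the planted poly(dA:dT) edges
        inside = prof.mean[(prof.offsets < -15) & (prof.offsets >= -60)]
        flank = prof.mean[(prof.offsets > 0) & (prof.offsets <= 300)]
        counts = prof.count[(prof.offsets > 0) & (prof.offsets <= 300)]
        assert np.nanmean(inside) == pytest.approx(truth.barrier_gc, abs=0.01)
        flank_mean = np.nansum(flank * counts) / counts.sum()
        assert flank_mean == pytest.approx(truth.flank_gc, abs=0.01)


class TestSmooth:
    def _profile(self, mean, count=None):
        n = len(mean)
        offs = np.arange(-(n // 2), n - n // 2)
        count = np.ones(n) if count is None else count
        return BorderAlignedProfile(offs, np.asarray(mean, float), count)

    def test_window_one_identity(self):
        p = self._profile([1, 2, 3, 4.0])
        assert np.allclose(smooth(p, 1).mean, p.mean)

    def test_constant_unchanged(self):
        p = self._profile(np.full(50, 3.3))
        assert np.allclose(smooth(p, 10).mean, 3.3)

    def test_step_becomes_ramp(self):
        m = np.concatenate([np.zeros(30), np.ones(30)])
        sm = smooth(self._profile(m), 10).mean
        interior = sm[25:35]
        assert (np.diff(interior) > 0).all()   # strictly increasing across the step
        assert sm[20] == 0.0 and sm[40] == 1.0

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-100, 100), st.integers(2, 15))
    def test_commutes_with_constant_shift(self, c, w):
        rng = np.random.default_rng(0)
        m = rng.random(60)
        base = smooth(self._profile(m), w).mean
        shifted = smooth(self._profile(m + c), w).mean
        assert np.allclose(shifted, base + c)

    def test_zero_count_sites_ignored(self):
        count = np.ones(20)
        count[5] = 0
        m = np.ones(20)
        m[5] = np.nan
        sm = smooth(self._profile(m, count), 5)
        assert np.allclose(sm.mean, 1.0)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            smooth(self._profile([1.0, 2.0]), 0)


class TestSymmetrize:
    def _profile(self, mean, count):
        offs = np.arange(len(mean))
        return BorderAlignedProfile(offs, np.asarray(mean, float),
                                    np.asarray(count, float))

    def test_idempotent_on_identical_sides(self):
        p = self._profile([1, 2, 3], [5, 5, 5])
        out = symmetrize(p, self._profile([1, 2, 3], [5, 5, 5]))
        assert np.allclose(out.mean, [1, 2, 3])

    def test_left_only_passes_through(self):
        left = self._profile([1, 2, 3], [4, 4, 4])
        right = self._profile([np.nan] * 3, [0, 0, 0])
        out = symmetrize(left, right, mode="revcomp_average")
        assert np.allclose(out.mean, left.mean)

    def test_count_weighted(self):
        out = symmetrize(self._profile([0.0], [1]), self._profile([1.0], [3]))
        assert out.mean[0] == pytest.approx(0.75)

    def test_axis_mismatch(self):
        a = self._profile([1, 2], [1, 1])
        b = BorderAlignedProfile(np.array([5, 6]), np.array([1.0, 2.0]),
                                 np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            symmetrize(a, b)


class TestHeatMap:
    def test_single_tag_smears_to_length_two(self):
        track = TagTrack({"chr1": np.zeros(200, dtype=np.int32)})
        track.counts["chr1"][100] = 1
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150],
                                "d": [100]})
        hm = tag_heatmap(track, regions, group_size=1, display_width=100)
        row = hm.values[0]
        covered = np.flatnonzero(row == 1.0)
        assert len(covered) == 2   # segment of length 2*1 around the locus

    def test_no_tags_all_zero(self):
        track = TagTrack({"chr1": np.zeros(300, dtype=np.int32)})
        regions = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 200],
                                "end": [100, 300], "d": [100, 100]})
        hm = tag_heatmap(track, regions, group_size=2)
        assert np.nansum(hm.values) == 0.0

    def test_row_mean_invariant_to_group_permutation(self, rng):
        vals = {f"r{i}": rng.random(100) for i in range(6)}

        def get(chrom, start, end):
            return vals[chrom]

        regions = pd.DataFrame({"chrom": list(vals), "start": 0, "end": 100,
                                "d": 100})
        hm1 = build_heatmap(get, regions, group_size=6, display_width=98)
        hm2 = build_heatmap(get, regions.iloc[::-1], group_size=6,
                            display_width=98)
        assert np.allclose(hm1.values, hm2.values, equal_nan=True)


class TestPolynucleotide:
    def test_full_overlap(self):
        codes = np.array([0, 0, 0, 0, 0], dtype=np.uint8)   # AAAAA
        assert polynucleotide_coverage(codes, 0, 3).all()

    def test_absent_motif(self):
        codes = np.array([0, 1, 0, 1, 0], dtype=np.uint8)
        assert not polynucleotide_coverage(codes, 0, 3).any()

    def test_generator_edges_peak_at_borders(self):
        from niebtools.simulate import SyntheticTruth, generate_genomes
        truth = SyntheticTruth()
        genome, catalog = generate_genomes(truth, {"chr1": 1_000_000}, seed=4)
        profs = polynucleotide_profile(genome, catalog, 150, ks=(5,),
                                       masked=False)
        a5 = profs["AAAAA"].mean
        offs = profs["AAAAA"].offsets
        edge = np.nanmean(a5[(offs >= -5) & (offs <= -1)])
        distal = np.nanmean(a5[(offs >= 100) & (offs <= 150)])
        assert edge > 5 * distal


class TestTssProfile:
    def test_strand_flip_mirrors(self):
        vals = {"chr1": np.arange(100, dtype=float)}
        plus = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [80],
                             "strand": ["+"]})
        minus = pd.DataFrame({"chrom": ["chr1"], "start": [20], "end": [51],
                              "strand": ["-"]})
        p = tss_profile(vals, plus, 10)["all"]
        m = tss_profile(vals, minus, 10)["all"]
        # anchored at 50 both ways; minus orientation flips the axis
        assert np.allclose(p["value"].to_numpy(),
                           m["value"].to_numpy()[::-1])

    def test_unstranded_excluded(self):
        vals = {"chr1": np.ones(100)}
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [80],
                              "strand": ["."]})
        prof = tss_profile(vals, genes, 10)["all"]
        assert prof["n"].sum() == 0
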