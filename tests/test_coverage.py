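import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introcap.coverage as cov
from oracles import interval_jaccard_by_bases


def _profile(acc, depths, bin_width=10, chrom="chr1"):
    df = cov.bin_coverage(np.asarray(depths), bin_width)
    df.insert(0, "chrom", chrom)
    return cov.CoverageProfile(acc, df, bin_width)


class TestDepthPerBase:
    def test_no_alignments_all_zero(self):
        depth = cov.depth_from_starts(np.empty(0, dtype=int), 150, 1000)
        assert depth.shape == (1000,)
        assert not depth.any()

    def test_one_pair_covers_exactly_its_mates(self):
        depth = cov.depth_from_starts(np.array([100, 400]), 150, 1000)
        assert (depth[100:250] == 1).all()
        assert (depth[400:550] == 1).all()
        assert depth.sum() == 300

    def test_depth_sum_counting_identity(self, rng):
        # sum(depth) == n_mates * read_len, overlapping mates counted twice
        starts = rng.integers(0, 850, size=200)
        depth = cov.depth_from_starts(starts, 150, 1000)
        assert depth.sum() == 200 * 150

    def test_out_of_bounds_alignment_rejected(self):
        with pytest.raises(ValueError):
            cov.depth_from_starts(np.array([950]), 150, 1000)


class TestBinCoverage:
    def test_all_zero_depth(self):
        df = cov.bin_coverage(np.zeros(95, dtype=int), 10)
        assert (df["mean_depth"] == 0).all()
        assert df["bin_end"].iloc[-1] == 95

    def test_constant_depth_including_short_last_bin(self):
        df = cov.bin_coverage(np.full(95, 3), 10)
        assert (df["mean_depth"] == 3).all()
        assert df["bin_end"].iloc[-1] - df["bin_start"].iloc[-1] == 5

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=300),
        st.integers(min_value=1, max_value=64),
    )
    def test_conservation_identity(self, depths, bin_width):
        # sum over bins of mean * length reproduces sum(depth) exactly
        depth = np.array(depths, dtype=float)
        df = cov.bin_coverage(depth, bin_width)
        total = (df["mean_depth"] * (df["bin_end"] - df["bin_start"])).sum()
        assert total == pytest.approx(depth.sum())


class TestNormalizeProfiles:
    def test_identical_profiles_have_unit_ratio(self):
        depths = np.tile([2, 4, 6, 8], 25)
        profiles = [_profile(a, depths) for a in "ABC"]
        tidy = cov.normalize_profiles(profiles)
        assert np.allclose(tidy["ratio"], 1.0)

    def test_halved_bin_has_half_ratio(self):
        # A's first bin at exactly half the cohort's *scaled* level: its
        # other bins are raised so A's genome-wide mean stays at 4
        base = np.full(100, 4.0)
        low = np.full(100, (4.0 * 100 - 2.0 * 10) / 90)
        low[:10] = 2.0
        profiles = [_profile("A", low), _profile("B", base), _profile("C", base)]
        tidy = cov.normalize_profiles(profiles)
        first = tidy[(tidy["accession"] == "A") & (tidy["bin_start"] == 0)]
        assert first["ratio"].iloc[0] == pytest.approx(0.5)

    def test_ratio_invariant_to_library_size(self, rng):
        depths = rng.integers(1, 20, size=200).astype(float)
        others = [rng.integers(1, 20, size=200).astype(float) for _ in range(2)]
        for const in (0.5, 3.0, 17.0):
            a = cov.normalize_profiles(
                [_profile("A", depths), _profile("B", others[0]), _profile("C", others[1])]
            )
            b = cov.normalize_profiles(
                [_profile("A", depths * const), _profile("B", others[0]), _profile("C", others[1])]
            )
            assert np.allclose(
                a[a["accession"] == "A"]["ratio"],
                b[b["accession"] == "A"]["ratio"],
                equal_nan=True,
            )

    def test_small_cohort_refused(self):
        profiles = [_profile(a, np.ones(50)) for a in "AB"]
        with pytest.raises(ValueError):
            cov.normalize_profiles(profiles)

    def test_zero_median_bins_undefined(self):
        depths = np.ones(100)
        depths[:10] = 0
        profiles = [_profile(a, depths) for a in "ABC"]
        tidy = cov.normalize_profiles(profiles)
        first = tidy[tidy["bin_start"] == 0]
        assert not first["defined"].any()


class TestCallDrops:
    def _normalized(self, ratios, defined=None):
        n = len(ratios)
        return pd.DataFrame(
            {
                "accession": "A",
                "chrom": "chr1",
                "bin_start": np.arange(n) * 10,
                "bin_end": (np.arange(n) + 1) * 10,
                "mean_depth": 1.0,
                "scaled": 1.0,
                "ratio": ratios,
                "defined": [True] * n if defined is None else defined,
            }
        )

    def test_flat_profile_no_calls(self):
        assert cov.call_drops(self._normalized([1.0] * 20)) == []

    def test_zero_alpha_never_calls(self):
        assert cov.call_drops(self._normalized([0.0] * 20), alpha=0.0) == []

    def test_run_of_low_bins_called_with_min_bins(self):
        ratios = [1, 1, 0.1, 0.1, 0.1, 1, 0.1, 1, 1]
        calls = cov.call_drops(self._normalized(ratios), alpha=0.5, min_bins=2)
        assert len(calls) == 1  # the isolated single bin is not called
        assert (calls[0].start, calls[0].end, calls[0].n_bins) == (20, 50, 3)

    def test_undefined_bins_break_runs(self):
        ratios = [0.1, 0.1, np.nan, 0.1, 0.1]
        defined = [True, True, False, True, True]
        calls = cov.call_drops(self._normalized(ratios, defined))
        assert [(c.start, c.end) for c in calls] == [(0, 20), (30, 50)]


class TestAnnotateDrops:
    def test_overlap_and_jaccard_arithmetic(self):
        call = cov.DropCall("A", "chr1", 0, 10, 0.1, 1)
        cov.annotate_drops([call], [("chr1", 5, 15, "known")])
        assert call.annotations == [
            {"label": "known", "overlap": 5, "jaccard": pytest.approx(5 / 15)}
        ]

    def test_empty_known_list(self):
        call = cov.DropCall("A", "chr1", 0, 10, 0.1, 1)
        cov.annotate_drops([call], [])
        assert call.annotations == []

    def test_matches_per_base_set_oracle(self, rng):
        for _ in range(100):
            a = sorted(rng.integers(0, 500, size=2).tolist())
            b = sorted(rng.integers(0, 500, size=2).tolist())
            if a[0] == a[1] or b[0] == b[1]:
                continue
            ov, jac = cov.interval_overlap(tuple(a), tuple(b))
            ov2, jac2 = interval_jaccard_by_bases(tuple(a), tuple(b))
            assert ov == ov2
            assert jac == pytest.approx(jac2)

    def test_malformed_bed_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\tok\nchr1\t50\tnope\n")
        with pytest.raises(ValueError, match="line 2"):
            cov.read_bed(path)
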