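"""FSR and breakpoint-score extraction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from comos.fragmentomics import (
    BreakpointProfile,
    build_fsr_table,
    compute_breakpoint_profile,
    compute_fsr,
    profile_feature_vector,
)
from comos.genome import ChromSizes, tile_genome

from conftest import random_fragments


def frags(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["length"] = df["end"] - df["start"]
    return df


def brute_force_fsr(fragments, bins, fraction=0.5):
    """Classify every fragment independently, then take per-bin ratios."""
    from comos.genome import assign_interval_to_bins

    short = np.zeros(len(bins))
    long = np.zeros(len(bins))
    for row in fragments.itertuples():
        length = row.end - row.start
        if not 100 <= length <= 220:
            continue
        idx = assign_interval_to_bins(row.chrom, row.start, row.end, bins, fraction)
        if idx is None:
            continue
        if length <= 150:
            short[idx] += 1
        else:
            long[idx] += 1
    return np.where(long > 0, short / np.maximum(long, 1), np.nan)


def brute_force_profile(fragments, regions, half_window):
    """O(n*m) double loop over all (fragment, region) pairs."""
    counts = np.zeros(2 * half_window + 1)
    for f in fragments.itertuples():
        for r in regions.itertuples():
            if f.chrom != r.chrom:
                continue
            off = f.start - r.center
            if abs(off) <= half_window:
                counts[off + half_window] += 1
    total = counts.sum()
    return counts / total if total else counts


class TestFsr:
    @pytest.fixture()
    def bins(self):
        return tile_genome(ChromSizes([("chr1", 10_000_000)]), 5_000_000)

    def test_short_to_long_ratio(self, bins):
        f = frags([("chr1", 0, L) for L in (120, 140, 130, 180, 200)])
        vec = compute_fsr(f, bins)
        assert vec.values[0] == pytest.approx(1.5)

    def test_zero_short_count_gives_zero(self, bins):
        vec = compute_fsr(frags([("chr1", 0, 160), ("chr1", 0, 170)]), bins)
        assert vec.values[0] == 0.0

    def test_zero_long_count_is_missing_not_zero(self, bins):
        vec = compute_fsr(frags([("chr1", 0, 120)]), bins)
        assert np.isnan(vec.values[0])

    def test_out_of_range_lengths_discarded(self, bins):
        f = frags([("chr1", 0, 99), ("chr1", 0, 221), ("chr1", 0, 120), ("chr1", 0, 180)])
        assert compute_fsr(f, bins).values[0] == pytest.approx(1.0)

    def test_empty_fragments_warns_all_missing(self, bins, caplog):
        vec = compute_fsr(frags([]), bins)
        assert np.isnan(vec.values).all()

    def test_matches_brute_force_oracle(self, rng):
        sizes = ChromSizes([("chr1", 9_500_000), ("chr2", 4_200_000)])
        bins = tile_genome(sizes, 2_000_000)
        f = random_fragments(rng, sizes, 5_000, min_len=90, max_len=240)
        got = compute_fsr(f, bins).values
        expected = brute_force_fsr(f, bins)
        np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
        np.testing.assert_allclose(got[~np.isnan(got)], expected[~np.isnan(expected)])

    def test_input_order_and_duplication_invariance(self, rng):
        sizes = ChromSizes([("chr1", 6_000_000)])
        bins = tile_genome(sizes, 2_000_000)
        f = random_fragments(rng, sizes, 500, min_len=100, max_len=220)
        base = compute_fsr(f, bins).values
        shuffled = compute_fsr(f.sample(frac=1, random_state=3), bins).values
        doubled = compute_fsr(pd.concat([f, f]), bins).values
        np.testing.assert_allclose(shuffled, base)
        np.testing.assert_allclose(doubled, base)


def regions_df(rows, label="nucleosome"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["center"] = (df["start"] + df["end"]) // 2
    df["class_label"] = label
    return df


class TestBreakpointProfile:
    def test_single_fragment_at_center(self):
        reg = regions_df([("chr1", 900, 1100)])  # center 1000
        prof = compute_breakpoint_profile(frags([("chr1", 1000, 1160)]), reg, 200)
        assert prof.scores[200] == 1.0
        assert prof.scores.sum() == 1.0

    def test_scores_sum_to_one_when_nonempty(self, rng):
        sizes = ChromSizes([("chr1", 1_000_000)])
        reg = regions_df([("chr1", c, c + 147) for c in range(10_000, 500_000, 20_000)])
        f = random_fragments(rng, sizes, 3_000, min_len=100, max_len=200)
        prof = compute_breakpoint_profile(f, reg, 300)
        assert prof.scores.sum() == pytest.approx(1.0, abs=1e-12)
        assert (prof.scores >= 0).all()

    def test_no_breakpoints_flags_empty(self):
        reg = regions_df([("chr2", 900, 1100)])
        prof = compute_breakpoint_profile(frags([("chr1", 0, 150)]), reg, 200)
        assert prof.empty and (prof.scores == 0).all()

    def test_matches_brute_force_double_loop(self, rng):
        sizes = ChromSizes([("chr1", 800_000), ("chr2", 500_000)])
        centers = rng.integers(5_000, 450_000, 100)
        reg = regions_df([
            ("chr1" if i % 2 else "chr2", int(c), int(c) + 200) for i, c in enumerate(centers)
        ])
        reg = reg.sort_values(["chrom", "start"]).reset_index(drop=True)
        f = random_fragments(rng, sizes, 4_000, min_len=100, max_len=200)
        got = compute_breakpoint_profile(f, reg, 150).scores
        np.testing.assert_allclose(got, brute_force_profile(f, reg, 150))

    def test_uniform_starts_give_flat_profile(self, rng):
        # binomial expectation: each offset ~ 1/(2w+1) within 3 SE
        w = 200
        n = 50_000
        center = 500_000
        starts = rng.integers(center - w, center + w + 1, n)
        f = frags([("chr1", int(s), int(s) + 160) for s in starts])
        reg = regions_df([("chr1", center - 73, center + 74)])
        prof = compute_breakpoint_profile(f, reg, w)
        p = 1 / (2 * w + 1)
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(prof.scores - p) <= 3 * se + 1e-12)

    def test_order_and_duplication_invariance(self, rng):
        sizes = ChromSizes([("chr1", 400_000)])
        reg = regions_df([("chr1", c, c + 147) for c in range(10_000, 350_000, 30_000)])
        f = random_fragments(rng, sizes, 1_000, min_len=100, max_len=200)
        base = compute_breakpoint_profile(f, reg, 200).scores
        shuf = compute_breakpoint_profile(f.sample(frac=1, random_state=9), reg, 200).scores
        dup = compute_breakpoint_profile(pd.concat([f, f]), reg, 200).scores
        np.testing.assert_allclose(shuf, base)
        np.testing.assert_allclose(dup, base)


class TestProfileFeatureVector:
    def make_profile(self, scores):
        scores = np.asarray(scores, dtype=float)
        hw = (len(scores) - 1) // 2
        return BreakpointProfile("s", "nucleosome", hw, scores)

    def test_identity_at_bin_one(self, rng):
        scores = rng.dirichlet(np.ones(401))
        prof = self.make_profile(scores)
        np.testing.assert_array_equal(profile_feature_vector(prof, 1), scores)

    def test_constant_profile_stays_constant(self):
        prof = self.make_profile(np.full(401, 1 / 401))
        out = profile_feature_vector(prof, 7)
        np.testing.assert_allclose(out, 1 / 401)

    def test_window_means_match_oracle_with_remainder_dropped(self, rng):
        scores = rng.dirichlet(np.ones(401))
        prof = self.make_profile(scores)
        out = profile_feature_vector(prof, 5)
        assert len(out) == 80
        expected = [scores[i * 5:(i + 1) * 5].mean() for i in range(80)]
        np.testing.assert_allclose(out, expected)

    def test_invalid_smoothing_rejected(self):
        with pytest.raises(ValueError):
            profile_feature_vector(self.make_profile(np.ones(5) / 5), 0)


class TestFsrTable:
    def test_missingness_filter_and_train_mean_imputation(self):
        bins = tile_genome(ChromSizes([("chr1", 10_000_000)]), 5_000_000)
        # bin 1 has long fragments only for sample a; missing for b and c
        fr = {
            "a": frags([("chr1", 0, 120), ("chr1", 0, 180),
                        ("chr1", 6_000_000, 6_000_120), ("chr1", 6_000_000, 6_000_180)]),
            "b": frags([("chr1", 0, 130), ("chr1", 0, 190)]),
            "c": frags([("chr1", 0, 110), ("chr1", 0, 200)]),
        }
        # bin 1 missing in 2/3 of train -> dropped
        table = build_fsr_table(fr, bins, train_samples=["a", "b", "c"],
                                max_missing_bin_fraction=0.2)
        assert list(table.columns) == ["fsr_bin0"]
        assert not table.isna().any().any()

    def test_imputation_uses_training_mean_only(self):
        bins = tile_genome(ChromSizes([("chr1", 5_000_000)]), 5_000_000)
        fr = {
            "t1": frags([("chr1", 0, 120), ("chr1", 0, 180)]),   # fsr 1.0
            "t2": frags([("chr1", 0, 120), ("chr1", 0, 130), ("chr1", 0, 180)]),  # 2.0
            "v1": frags([("chr1", 0, 120)]),  # missing (no long)
        }
        table = build_fsr_table(fr, bins, train_samples=["t1", "t2"],
                                max_missing_bin_fraction=0.5)
        assert table.loc["v1", "fsr_bin0"] == pytest.approx(1.5)
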