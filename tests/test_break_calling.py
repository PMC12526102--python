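import numpy as np
import pytest
from scipy import stats

from mtdna_breaks.break_calling import (
    DEFAULT_STALLING_SITES,
    background_subtract,
    calls_to_frame,
    circular_running_median,
    classify_calls,
    rank_top_bins,
    ssb_differential,
    stalling_site_query,
)
from mtdna_breaks.end_profiling import (
    BinnedEndProfile,
    bin_ends,
    extract_ends,
    mean_depth,
    normalize_to_depth,
)
from mtdna_breaks.genome_model import CircularGenome, RegionSet, CircularInterval, human_mtdna_regions
from mtdna_breaks.synthetic_data import BreakSpec, SimulationConfig, simulate_paired_libraries
from conftest import RECOVERY_DSB, RECOVERY_NICKS
from _oracles import brute_circular_median

L = 16569


def make_profile(upstream, downstream=None, normalized="per_depth", width=40, length=L):
    up = np.asarray(upstream, dtype=float)
    down = up.copy() if downstream is None else np.asarray(downstream, dtype=float)
    return BinnedEndProfile(length, width, up, down, normalized)


class TestSSBDifferential:
    def test_equal_profiles_give_zero_ssb(self):
        p = make_profile(np.full(415, 0.004))
        ssb = ssb_differential(p, p)
        assert not ssb.upstream.any() and not ssb.downstream.any()
        assert ssb.clamped_upstream_bins == 0

    def test_difference_arithmetic(self):
        s1 = make_profile(np.full(415, 0.010))
        native = make_profile(np.full(415, 0.004))
        assert ssb_differential(s1, native).upstream[0] == pytest.approx(0.006)

    def test_negative_differences_clamped_and_counted(self):
        s1 = make_profile(np.zeros(415))
        native = make_profile(np.r_[0.01, np.zeros(414)])
        ssb = ssb_differential(s1, native)
        assert ssb.upstream[0] == 0.0
        assert ssb.clamped_upstream_bins == 1 and ssb.clamped_downstream_bins == 1
        assert ssb.clamped_mass == pytest.approx(0.02)

    def test_reconstruction_where_unclamped(self):
        rng = np.random.default_rng(4)
        native = make_profile(rng.random(415) * 1e-3)
        s1 = make_profile(native.upstream + rng.random(415) * 1e-3, native.downstream + 1e-4)
        ssb = ssb_differential(s1, native)
        assert np.allclose(ssb.upstream + native.upstream, s1.upstream)

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssb_differential(make_profile(np.zeros(415)), make_profile(np.zeros(400), width=41))
        with pytest.raises(ValueError):
            ssb_differential(
                make_profile(np.zeros(415)),
                make_profile(np.zeros(415), normalized="raw_counts"),
            )

    def test_requires_nick_hotspot_visible_only_after_s1(self):
        config = SimulationConfig(
            hotspots=[BreakSpec(8000, "nick_heavy", 0.2)],
            background_nick_rate=1e-5,
            n_molecules=1500,
            seed=3,
        )
        native, treated = simulate_paired_libraries(config)
        excl = human_mtdna_regions()["EagI_exclusion"]

        def per_depth(frags):
            table = extract_ends(frags, L, excl)
            return normalize_to_depth(bin_ends(table, 40), mean_depth(frags, L))

        ssb = ssb_differential(per_depth(treated), per_depth(native))
        peak_bin = 8000 // 40  # upstream ends at 8001 fall in 0-based bin 200
        assert np.argmax(ssb.upstream) == peak_bin


class TestRunningMedianResiduals:
    def test_matches_brute_force_circular_median(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(8, 200))
            w = int(rng.integers(1, n // 2 + 1))
            values = rng.random(n)
            assert np.allclose(
                circular_running_median(values, w), brute_circular_median(values.tolist(), w)
            )

    def test_constant_profile_gives_zero_residuals(self):
        res = background_subtract(make_profile(np.full(415, 0.3)), 25)
        assert np.allclose(res.upstream, 0.0)

    def test_single_spike_residual_equals_height(self):
        values = np.zeros(415)
        values[100] = 7.5
        res = background_subtract(make_profile(values), 5)
        assert res.upstream[100] == pytest.approx(7.5)
        assert np.allclose(np.delete(res.upstream, 100), 0.0)

    def test_two_bin_plateau_on_constant_background(self):
        values = np.full(101, 2.0)
        values[50:52] = 9.0
        res = background_subtract(make_profile(values, length=101 * 40), 5)
        assert np.allclose(res.upstream[50:52], 7.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(8)
        values = rng.random(415)
        r1 = background_subtract(make_profile(values), 25).upstream
        r2 = background_subtract(make_profile(values + 3.7), 25).upstream
        assert np.allclose(r1, r2)

    def test_window_bounds_checked(self):
        with pytest.raises(ValueError):
            background_subtract(make_profile(np.zeros(415)), 0)
        with pytest.raises(ValueError):
            background_subtract(make_profile(np.zeros(415)), 300)


class TestRanking:
    def test_tie_break_is_coordinate_order(self):
        res = background_subtract(make_profile(np.full(415, 1.0)), 25)
        calls = rank_top_bins(res, "upstream", None, 5)
        assert [c.bin_index for c in calls] == [0, 1, 2, 3, 4]
        assert [c.rank for c in calls] == [1, 2, 3, 4, 5]

    def test_excluded_region_spike_absent(self):
        values = np.zeros(415)
        values[5790 // 40] = 5.0  # inside oriL 5770-5820
        values[200] = 1.0
        res = background_subtract(make_profile(values), 25)
        exclude = human_mtdna_regions().subset(["D-loop", "oriL"])
        calls = rank_top_bins(res, "upstream", exclude, 15)
        assert all(c.bin_index != 5790 // 40 for c in calls)
        assert calls[0].bin_index == 200

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.random(415)
        res = background_subtract(make_profile(values), 25)
        scaled = background_subtract(make_profile(values * 137.0), 25)
        a = [(c.bin_index, c.rank) for c in rank_top_bins(res, "upstream", None, 15)]
        b = [(c.bin_index, c.rank) for c in rank_top_bins(scaled, "upstream", None, 15)]
        assert a == b

    def test_fewer_eligible_than_n_top(self):
        regions = RegionSet(L, [CircularInterval(41, 16569, "most")])
        res = background_subtract(make_profile(np.zeros(415)), 25)
        calls = rank_top_bins(res, "upstream", regions, 15)
        assert len(calls) == 1 and calls[0].bin_index == 0  # only bin 1-40 eligible

    def test_classification_from_differential_and_native(self, recovery_run):
        _, _, _, result = recovery_run
        by_bin = {c.bin_index: c for c in result.calls}
        for nick_pos in RECOVERY_NICKS:
            assert by_bin[nick_pos // 40].break_class == "SSB"

    def test_calls_frame_columns(self, recovery_run):
        frame = calls_to_frame(recovery_run[3].calls)
        assert list(frame["rank"]) == sorted(frame["rank"])
        assert {"bin_start", "end_class", "residual", "break_class"} <= set(frame.columns)


class TestNickHotspotsInvisibleNatively:
    def test_native_profile_consistent_with_background_at_nick_bins(self, recovery_run):
        """Two-sided binomial check (alpha 0.01, Bonferroni over the nick
        bins): native upstream counts at nick-only hotspot bins look like
        uniform background."""
        _, native, _, result = recovery_run
        counts = np.rint(result.native_profile.upstream * result.native_depth).astype(int)
        # eligible background: bins far from the planted DSB and the EagI shadow
        nick_bins = [p // 40 for p in RECOVERY_NICKS]
        total = int(counts.sum())
        alpha = 0.01 / len(nick_bins)
        for b in nick_bins:
            p = stats.binomtest(int(counts[b]), total, 1 / counts.size).pvalue
            assert p > alpha


class TestStallingSiteQuery:
    def test_default_panel(self):
        assert DEFAULT_STALLING_SITES == (
            (3210, "upstream"),
            (5736, "upstream"),
            (5969, "upstream"),
            (9921, "downstream"),
            (14249, "downstream"),
        )

    def test_empty_library_zero_frequencies(self):
        table = extract_ends([], L, None)
        out = stalling_site_query(end_table=table, depth=1.0)
        assert (out.frequency == 0).all()
        assert (out["mode"] == "per_position").all()

    def test_binned_mode_uses_containing_bin(self):
        values = np.zeros(415)
        values[3209 // 40] = 0.123
        profile = make_profile(values)
        out = stalling_site_query([(3210, "upstream")], profile=profile)
        assert out.frequency[0] == pytest.approx(0.123)
        assert out["mode"][0] == "binned"

    def test_simulated_dsb_truth_recovery(self):
        """A DSB hotspot at 5736 produces upstream ends at 5737 and downstream
        ends at 5736 at the hotspot rate, within 3 binomial SEs."""
        rate, n = 0.2, 4000
        config = SimulationConfig(
            hotspots=[BreakSpec(5736, "dsb", rate)],
            background_nick_rate=0.0,
            eagI_efficiency=1.0,
            n_molecules=n,
            seed=9,
        )
        native, _ = simulate_paired_libraries(config)
        table = extract_ends(native, L, human_mtdna_regions()["EagI_exclusion"])
        depth = mean_depth(native, L)
        out = stalling_site_query(
            [(5737, "upstream"), (5736, "downstream")], end_table=table, depth=depth
        )
        # depth ~ n (every molecule EagI-linearized), truth frequency = rate*n/depth
        expected = rate * n / depth
        se = np.sqrt(rate * (1 - rate) * n) / depth
        for freq in out.frequency:
            assert abs(freq - expected) < 3 * se

    def test_unknown_end_class_rejected(self):
        with pytest.raises(ValueError):
            stalling_site_query([(100, "sideways")], profile=make_profile(np.zeros(415)))
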