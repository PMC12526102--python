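import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtdna_breaks.end_profiling import (
    BinnedEndProfile,
    NormalizationError,
    SizeDistribution,
    bin_ends,
    compare_size_distributions,
    default_size_edges,
    extract_ends,
    length_bias_weights,
    mean_depth,
    normalize_to_depth,
    profile_to_frame,
    read_fragments_bed,
    read_profile_tsv,
    select_reference_library,
    write_profile_tsv,
)
from mtdna_breaks.genome_model import CircularGenome, CircularInterval
from mtdna_breaks.synthetic_data import (
    FragmentRecord,
    SimulationConfig,
    rotate_fragments,
    sample_library,
)
from _oracles import brute_bin_counts

L = 16569
EAGI = CircularInterval(2550, 2585, "EagI_exclusion")


def mito(up, down):
    return FragmentRecord(up, down, (down - up) % L + 1, "mito", up > down)


class TestExtractEnds:
    def test_full_length_fragment_ends_both_excluded(self):
        table = extract_ends([mito(2568, 2567)], L, EAGI)
        assert table.upstream == [] and table.downstream == []
        assert table.excluded_upstream == 1 and table.excluded_downstream == 1

    def test_partial_exclusion(self):
        table = extract_ends([mito(3211, 2567)], L, EAGI)
        assert table.upstream == [3211] and table.downstream == []
        assert table.excluded == 1

    def test_empty_input(self):
        table = extract_ends([], L, EAGI)
        assert table.upstream == [] and table.downstream == [] and table.excluded == 0

    def test_nuclear_records_ignored(self):
        table = extract_ends([FragmentRecord(None, None, 8000, "nuclear")], L, EAGI)
        assert table.upstream == [] and table.excluded == 0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_end_conservation(self, seed):
        lib = sample_library(
            SimulationConfig(background_nick_rate=2e-5, n_molecules=30, seed=seed)
        )
        table = extract_ends(lib, L, EAGI)
        n_mito = sum(f.compartment == "mito" for f in lib)
        assert len(table.upstream) + len(table.downstream) + table.excluded == 2 * n_mito


class TestBinning:
    def test_bin_boundary_convention(self):
        table = extract_ends([mito(40, 41)], L, None)
        profile = bin_ends(table, 40)
        assert profile.upstream[0] == 1  # position 40 -> bin 1
        assert profile.downstream[1] == 1  # position 41 -> bin 2

    def test_bin_count_and_short_final_bin(self):
        profile = bin_ends(extract_ends([], L, None), 40)
        assert profile.n_bins == 415
        assert profile.bin_bounds(414) == (16561, 16569)  # width 9, kept
        assert profile.bin_bounds(0) == (1, 40)

    def test_bin_sums_equal_retained_ends(self):
        rng = np.random.default_rng(5)
        frags = [mito(int(a), int(b)) for a, b in rng.integers(1, L + 1, (1000, 2))]
        table = extract_ends(frags, L, EAGI)
        profile = bin_ends(table, 40)
        assert profile.upstream.sum() == len(table.upstream)
        assert profile.downstream.sum() == len(table.downstream)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(1, 200))
            w = int(rng.choice([7, 40, 160]))
            positions = rng.integers(1, L + 1, n).tolist()
            table = extract_ends([mito(p, p) for p in positions], L, None)
            profile = bin_ends(table, w)
            assert profile.upstream.tolist() == brute_bin_counts(positions, w, L)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bin_ends(extract_ends([], L, None), 0)


class TestDepthNormalization:
    def test_depth_examples(self):
        assert mean_depth([mito(2568, 2567)], L) == 1.0  # one full-length fragment
        two = [FragmentRecord(1, 3000, 3000), FragmentRecord(3001, 16569, 13569)]
        assert mean_depth(two, L) == 1.0
        assert mean_depth([], L) == 0.0

    def test_normalize_arithmetic(self):
        profile = bin_ends(extract_ends([mito(5, 6)] * 5, L, None), 40)
        normalized = normalize_to_depth(profile, 100.0)
        assert normalized.upstream[0] == pytest.approx(0.05)
        assert normalized.normalized == "per_depth"
        identity = normalize_to_depth(profile, 1.0)
        assert np.array_equal(identity.upstream, profile.upstream)

    def test_bad_depth_rejected(self):
        profile = bin_ends(extract_ends([], L, None), 40)
        with pytest.raises(NormalizationError):
            normalize_to_depth(profile, 0.0)

    def test_depth_normalization_removes_sampling_depth(self):
        # same break structure at 1x and 3x sampling depth -> same per-depth
        # profile up to Monte-Carlo error
        def profile_at(n, seed):
            lib = sample_library(
                SimulationConfig(
                    background_nick_rate=5e-5, s1_treated=True, n_molecules=n, seed=seed
                )
            )
            table = extract_ends(lib, L, EAGI)
            return normalize_to_depth(bin_ends(table, 40), mean_depth(lib, L))

        a = profile_at(2000, 1)
        b = profile_at(6000, 2)
        # totals agree within a few percent; bins are individually noisy
        assert a.upstream.sum() == pytest.approx(b.upstream.sum(), rel=0.1)

    def test_rotation_equivariance_when_bins_tile_the_circle(self):
        # L divisible by the bin width: rotating coordinates by whole bins
        # rotates the binned profile exactly
        Lr, shift = 16000, 4000
        rng = np.random.default_rng(17)
        frags = [
            FragmentRecord(int(a), int(b), (int(b) - int(a)) % Lr + 1, "mito")
            for a, b in rng.integers(1, Lr + 1, (500, 2))
        ]
        excl = CircularInterval(2550, 2585, "x")
        base = bin_ends(extract_ends(frags, Lr, excl), 40)
        rot = bin_ends(
            extract_ends(rotate_fragments(frags, shift, Lr), Lr, excl.rotated(shift, Lr)),
            40,
        )
        assert np.array_equal(np.roll(base.upstream, shift // 40), rot.upstream)
        assert np.array_equal(np.roll(base.downstream, shift // 40), rot.downstream)


class TestSizeDistributions:
    def test_proportions_sum_to_one(self):
        d = SizeDistribution.from_lengths([100, 600, 8000, 25000])
        assert d.proportions.sum() == pytest.approx(1.0)
        assert d.proportions[d.class_of(25000)] == 0.25  # overflow class

    def test_weights_identity(self):
        d = SizeDistribution.from_lengths([100, 600, 8000])
        w, degenerate = length_bias_weights(d, d)
        assert degenerate == []
        nz = d.proportions > 0
        assert np.allclose(w[nz], 1.0)

    def test_weights_ratio_oracle(self):
        edges = np.array([0, 10])
        sample = SizeDistribution(edges, [0.5, 0.5])
        reference = SizeDistribution(edges, [0.25, 0.75])
        w, _ = length_bias_weights(sample, reference)
        assert np.allclose(w, [0.5, 1.5])
        # reweighting the sample reproduces the reference exactly
        reweighted = sample.proportions * w
        assert np.allclose(reweighted / reweighted.sum(), reference.proportions)

    def test_zero_sample_class_reported(self):
        edges = np.array([0, 10])
        sample = SizeDistribution(edges, [1.0, 0.0])
        reference = SizeDistribution(edges, [0.5, 0.5])
        w, degenerate = length_bias_weights(sample, reference)
        assert w[1] == 0.0 and degenerate == [1]

    def test_mismatched_edges_rejected(self):
        a = SizeDistribution(np.array([0, 10]), [0.5, 0.5])
        b = SizeDistribution(np.array([0, 20]), [0.5, 0.5])
        with pytest.raises(ValueError):
            length_bias_weights(a, b)
        with pytest.raises(ValueError):
            compare_size_distributions(a, b)

    def test_select_reference_library(self):
        edges = np.array([0, 10000])
        one = SizeDistribution(edges, [0.9, 0.1])
        assert select_reference_library([one]) == 0
        libs = [
            SizeDistribution(edges, [0.9, 0.1]),
            SizeDistribution(edges, [0.6, 0.4]),
            SizeDistribution(edges, [0.8, 0.2]),
        ]
        assert select_reference_library(libs) == 1  # argmax of large-fragment mass
        tie = [SizeDistribution(edges, [0.8, 0.2]), SizeDistribution(edges, [0.8, 0.2])]
        assert select_reference_library(tie) == 0  # documented tie-break
        with pytest.raises(ValueError):
            select_reference_library([])

    def test_divergence_summary(self):
        edges = np.array([0, 10])
        a = SizeDistribution(edges, [0.6, 0.4])
        same = compare_size_distributions(a, a, full_length_bp=5)
        assert same.total_variation == 0.0 and same.full_length_difference == 0.0
        disjoint = compare_size_distributions(
            SizeDistribution(edges, [1.0, 0.0]), SizeDistribution(edges, [0.0, 1.0]), 5
        )
        assert disjoint.total_variation == 1.0
        b = SizeDistribution(edges, [0.4, 0.6])
        assert compare_size_distributions(a, b, 5).total_variation == pytest.approx(0.2)


class TestIO:
    def test_bed_conversion(self, tmp_path):
        path = tmp_path / "frags.bed"
        path.write_text(
            "chrM\t0\t16569\tmito\t0\n"  # full reference span
            "chrM\t3210\t5000\tmito\t0\n"  # 0-based half-open -> 3211..5000
            "chrM\t16000\t500\tmito\t1\n"  # flagged origin-spanning record
            "chrNuc\t0\t8000\tnuclear\t0\n"
        )
        frags = read_fragments_bed(path, L)
        assert (frags[0].upstream_end, frags[0].downstream_end, frags[0].length) == (1, 16569, L)
        assert (frags[1].upstream_end, frags[1].downstream_end, frags[1].length) == (3211, 5000, 1790)
        assert frags[2].origin_spanning and frags[2].length == L - 16000 + 500
        assert frags[3].compartment == "nuclear" and frags[3].length == 8000

    def test_bed_inverted_without_flag_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chrM\t16000\t500\tmito\t0\n")
        with pytest.raises(ValueError):
            read_fragments_bed(path, L)

    def test_profile_tsv_roundtrip(self, tmp_path):
        lib = sample_library(SimulationConfig(background_nick_rate=3e-5, n_molecules=50, seed=3))
        table = extract_ends(lib, L, EAGI)
        profile = normalize_to_depth(bin_ends(table, 40), mean_depth(lib, L))
        path = tmp_path / "profile.tsv"
        write_profile_tsv(profile, path, ["bin_width: 40"])
        back = read_profile_tsv(path, L)
        assert back.bin_width == 40
        assert np.allclose(back.upstream, profile.upstream)
        frame = profile_to_frame(profile)
        assert list(frame.columns) == ["bin", "bin_start", "bin_end", "upstream", "downstream"]
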