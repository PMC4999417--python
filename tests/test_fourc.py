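import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from finemapkit.fourc import (
    assign_reads,
    binned_profile,
    build_fragment_map,
    smooth_profile,
)


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def toy_map():
    return build_fragment_map({"chrT": _random_seq(21, 30_000)})


class TestFragmentMap:
    def test_cut_at_site_start_model(self):
        fmap = build_fragment_map({"s": "AAGATCAA"})
        frags = fmap.fragments
        assert [(r.start, r.end) for r in frags.itertuples()] == [(0, 2), (2, 8)]

    def test_blind_iff_no_secondary_site(self):
        # GATC at 0 and 14 -> fragments [0,14) and [14,20); AAGCTT at 6
        fmap = build_fragment_map({"s": "GATCTTAAGCTTGGGATCAA"})
        frags = fmap.fragments.set_index(["start", "end"])["blind"]
        assert not bool(frags.loc[(0, 14)])
        assert bool(frags.loc[(14, 20)])

    @given(st.integers(0, 2**32 - 1))
    def test_boundaries_match_independent_string_search(self, seed):
        seq = _random_seq(seed, 3_000)
        fmap = build_fragment_map({"s": seq})
        cuts = sorted(
            {0, len(seq)} | {i for i in range(len(seq)) if seq.startswith("GATC", i) and i > 0}
        )
        expected = list(zip(cuts[:-1], cuts[1:]))
        got = [(r.start, r.end) for r in fmap.fragments.itertuples()]
        assert got == expected

    def test_partition_property(self, toy_map):
        frags = toy_map.fragments
        assert (frags["end"] - frags["start"]).sum() == 30_000
        assert frags["start"].iloc[0] == 0
        assert (frags["start"].iloc[1:].to_numpy() == frags["end"].iloc[:-1].to_numpy()).all()

    def test_sequence_without_primary_site_is_single_fragment(self):
        fmap = build_fragment_map({"s": "AAAACCCCGGAA"})
        assert len(fmap.fragments) == 1

    def test_invalid_recognition_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_fragment_map({"s": "ACGT"}, primary="GAXC")


def _reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "mapq", "strand"])


class TestAssignReads:
    def test_all_low_quality_dropped(self, toy_map):
        reads = _reads([("chrT", i * 10, i * 10 + 50, f"r{i}", 10, "+") for i in range(20)])
        counts, rep = assign_reads(reads, toy_map)
        assert counts.sum() == 0
        assert rep["n_low_mapq"] == 20

    def test_duplicate_positions_collapse_to_unique(self, toy_map):
        reads = _reads(
            [("chrT", 100, 250, "a", 60, "+"), ("chrT", 100, 250, "b", 60, "+")]
        )
        counts, rep = assign_reads(reads, toy_map)
        assert counts.sum() == 1
        assert rep["n_duplicate"] == 1

    def test_five_prime_position_respects_strand(self, toy_map):
        # minus-strand read: 5' end is end-1
        reads = _reads([("chrT", 100, 250, "a", 60, "-"), ("chrT", 100, 250, "b", 60, "+")])
        counts, _ = assign_reads(reads, toy_map)
        assert counts.sum() == 2  # different 5' positions, both kept

    @given(st.integers(0, 2**32 - 1))
    def test_counts_match_brute_force_containment(self, seed):
        fmap = build_fragment_map({"s": _random_seq(5, 4_000)})
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        starts = rng.integers(0, 3_950, n)
        reads = _reads(
            [("s", int(s), int(s) + 50, f"r{i}", int(rng.integers(0, 61)), "+")
             for i, s in enumerate(starts)]
        )
        counts, _ = assign_reads(reads, fmap)
        uniq = {int(s) for s, q in zip(reads["start"], reads["mapq"]) if q >= 30}
        brute = np.zeros(len(fmap.fragments))
        for j, row in enumerate(fmap.fragments.itertuples()):
            brute[j] = sum(1 for s in uniq if row.start <= s < row.end)
        np.testing.assert_array_equal(counts, brute)

    def test_viewpoint_exclusion_and_mask(self, toy_map):
        reads = _reads(
            [
                ("chrT", 1_000, 1_150, "vp", 60, "+"),
                ("chrT", 5_000, 5_150, "msk", 60, "+"),
                ("chrT", 9_000, 9_150, "ok", 60, "+"),
            ]
        )
        counts, rep = assign_reads(
            reads,
            toy_map,
            viewpoint=("chrT", 900, 1_100),
            exclusion_radius=1_500,
            masked=[("chrT", 4_900, 5_200)],
        )
        assert counts.sum() == 1
        assert rep["n_masked_or_excluded"] == 2


class TestBinnedProfile:
    def test_uniform_spread_over_three_bins(self):
        fmap = build_fragment_map({"s": "A" * 300})  # single blind fragment [0, 300)
        counts = np.array([6.0])
        prof = binned_profile(counts, fmap, resolution=100)
        np.testing.assert_allclose(prof.bins["combined"], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(prof.bins["blind"], [2.0, 2.0, 2.0])
        np.testing.assert_allclose(prof.bins["nonblind"], 0.0)

    @given(st.integers(0, 2**32 - 1))
    def test_signal_conservation_and_per_base_oracle(self, seed):
        fmap = build_fragment_map({"s": _random_seq(6, 2_500)})
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, len(fmap.fragments)).astype(float)
        prof = binned_profile(counts, fmap, resolution=100)
        assert prof.bins["combined"].sum() == pytest.approx(counts.sum(), abs=1e-9)
        # per-base accumulation oracle
        per_base = np.zeros(2_500)
        for row, c in zip(fmap.fragments.itertuples(), counts):
            per_base[row.start : row.end] += c / (row.end - row.start)
        oracle = np.add.reduceat(per_base, np.arange(0, 2_500, 100))
        np.testing.assert_allclose(prof.bins["combined"], oracle, atol=1e-9)


class TestSmoothProfile:
    def _profile(self, values, resolution=100):
        from finemapkit.fourc import ContactProfile

        v = np.asarray(values, dtype=float)
        return ContactProfile("chrT", 0, resolution, {"combined": v, "blind": v * 0, "nonblind": v})

    def test_constant_profile_stays_constant(self):
        prof = smooth_profile(self._profile(np.full(200, 3.5)), window=5_000)
        np.testing.assert_allclose(prof.smoothed["combined"], 3.5, atol=1e-9)

    def test_spike_becomes_plateau(self):
        v = np.zeros(400)
        v[200] = 70.0
        prof = smooth_profile(self._profile(v), window=5_000)
        sm = prof.smoothed["combined"]
        plateau = sm[np.abs(sm - 70.0 / 50.0) < 1e-9]
        assert len(plateau) == 50  # window/resolution bins
        assert sm.max() == pytest.approx(70.0 / 50.0, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_with_mask(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(120) * 10
        masked = [(3_000, 4_500)]
        prof = smooth_profile(self._profile(v), window=1_000, masked=masked)
        sm = prof.smoothed["combined"]
        unmasked = np.ones(120, dtype=bool)
        unmasked[30:45] = False
        w = 10
        left = w // 2
        for i in range(120):
            j0, j1 = max(0, i - left), min(120, i - left + w)
            idx = np.arange(j0, j1)
            idx = idx[unmasked[idx]]
            if len(idx) == 0:
                assert np.isnan(sm[i])
            else:
                assert sm[i] == pytest.approx(v[idx].mean(), abs=1e-9)

    def test_window_smaller_than_resolution_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self._profile(np.ones(10)), window=50)

    def test_mean_preserved_over_interior(self):
        rng = np.random.default_rng(2)
        v = rng.random(500)
        prof = smooth_profile(self._profile(v), window=2_000)
        sm = prof.smoothed["combined"]
        # away from the edges the running mean redistributes but preserves mass
        assert sm[20:480].mean() == pytest.approx(v[10:490].mean(), rel=0.01)
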