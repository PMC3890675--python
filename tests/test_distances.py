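"""K2P distance computation against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodeval.distances import (
    DistanceMatrix,
    SitePairCounts,
    count_site_pairs,
    distance_matrix,
    k2p_distance,
    partition_distances,
    round_half_up,
    summarize,
)

from conftest import dataset_from, make_specimens, random_sequences

TRANSITIONS = {frozenset("AG"), frozenset("CT")}
MISSING = set("N-?")


def oracle_counts(a: str, b: str) -> tuple[int, int, int]:
    """Independent per-site double loop: (compared, transitions, transversions)."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in MISSING or y in MISSING:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def oracle_k2p(a: str, b: str) -> float:
    n, ts, tv = oracle_counts(a, b)
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return math.nan
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestCountSitePairs:
    def test_identical(self):
        c = count_site_pairs("ACGT", "ACGT")
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (4, 0, 0)

    def test_hand_count(self):
        a = "AAAAAAAAAACCCCCCCCCC"
        b = "GAAAAAAAAACCCCCCCCCA"
        c = count_site_pairs(a, b)
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (20, 1, 1)

    def test_gap_excluded(self):
        c = count_site_pairs("AC-T", "ACGT")
        assert (c.n_compared, c.n_transitions, c.n_transversions) == (3, 0, 0)

    @pytest.mark.parametrize("missing", ["N", "?", "-"])
    def test_missing_states_excluded_either_side(self, missing):
        c = count_site_pairs(f"A{missing}GT", "ACGT")
        assert c.n_compared == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_site_pairs("ACG", "ACGT")


class TestK2PDistance:
    def test_zero_when_no_substitutions(self):
        assert k2p_distance(SitePairCounts(100, 0, 0)) == 0.0

    def test_closed_form_spot_check(self):
        # P=0.1, Q=0.05: -1/2 ln(0.75) - 1/4 ln(0.9)
        d = k2p_distance(SitePairCounts(100, 10, 5))
        assert d == pytest.approx(0.1701811651, abs=1e-9)

    def test_saturation_undefined(self):
        assert math.isnan(k2p_distance(SitePairCounts(100, 50, 10)))
        assert math.isnan(k2p_distance(SitePairCounts(100, 0, 50)))

    def test_no_compared_sites_undefined(self):
        assert math.isnan(k2p_distance(SitePairCounts(0, 0, 0)))

    @given(st.integers(10, 500), st.integers(0, 200), st.integers(0, 200))
    def test_k2p_at_least_p_distance(self, n, ts, tv):
        """Multiple-hit correction can only inflate the observed distance."""
        if ts + tv > n:
            return
        c = SitePairCounts(n, ts, tv)
        d = k2p_distance(c)
        if not math.isnan(d):
            assert d >= c.P + c.Q - 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        ds = dataset_from(
            {"a": "ACGTAC", "b": "ACGTAC", "c": "ACGTAC"},
            {"a": "G x", "b": "G x", "c": "G y"},
        )
        m = distance_matrix(ds)
        assert np.allclose(m.d, 0.0)

    def test_two_sequence_closed_form(self):
        # 4 transitions among 1000 sites: -1/2 ln(1-0.008)
        a = "A" * 1000
        b = "G" * 4 + "A" * 996
        ds = dataset_from({"x": a, "y": b}, {"x": "G x", "y": "G y"})
        m = distance_matrix(ds)
        expected = -0.5 * math.log(1 - 0.008)
        assert m.get("x", "y") == pytest.approx(expected, abs=1e-12)
        raw = distance_matrix(ds, method="raw_substitutions")
        assert raw.get("x", "y") == 4

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for rep in range(5):
            seqs = random_sequences(rng, 8, 200, missing_prob=0.1)
            species = {sid: f"G sp{i % 3}" for i, sid in enumerate(seqs)}
            ds = dataset_from(seqs, species)
            mk = distance_matrix(ds, "K2P")
            mr = distance_matrix(ds, "raw_substitutions")
            labels = mk.labels
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = seqs[labels[i]], seqs[labels[j]]
                    n, ts, tv = oracle_counts(a, b)
                    assert mr.d[i, j] == ts + tv
                    want = oracle_k2p(a, b)
                    got = mk.d[i, j]
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_all_undefined_rejected(self):
        ds = dataset_from({"a": "NNNN", "b": "NNNN"}, {"a": "G x", "b": "G y"})
        with pytest.raises(ValueError, match="undefined"):
            distance_matrix(ds)

    def test_csv_roundtrip_with_na(self, tmp_path):
        d = np.array([[0.0, 0.5, np.nan], [0.5, 0.0, 0.1], [np.nan, 0.1, 0.0]])
        m = DistanceMatrix(labels=("a", "b", "c"), d=d)
        m.to_csv(tmp_path / "m.csv")
        back = DistanceMatrix.from_csv(tmp_path / "m.csv")
        assert back.labels == m.labels
        assert np.allclose(back.d, m.d, equal_nan=True)


class TestPartition:
    def test_two_by_two(self):
        ds = dataset_from(
            {"a1": "AAAAAAAA", "a2": "AAAAAAAT", "b1": "AAAAAAGG", "b2": "AAAAAAGA"},
            {"a1": "G a", "a2": "G a", "b1": "G b", "b2": "G b"},
        )
        parts = partition_distances(distance_matrix(ds), ds.specimens)
        assert len(parts.intra) == 2
        assert len(parts.inter) == 4

    def test_all_conspecific(self):
        ds = dataset_from(
            {"a": "AAAAAAAA", "b": "AAAAAAAT", "c": "AAAAAATT"},
            {"a": "G x", "b": "G x", "c": "G x"},
        )
        parts = partition_distances(distance_matrix(ds), ds.specimens)
        assert len(parts.inter) == 0
        assert len(parts.intra) == 3

    def test_singleton_contributes_no_intra(self):
        ds = dataset_from(
            {"a1": "AAAAAAAA", "a2": "AAAAAAAA", "x": "AAAAAAGT"},
            {"a1": "G a", "a2": "G a", "x": "G x"},
        )
        parts = partition_distances(distance_matrix(ds), ds.specimens)
        assert len(parts.intra) == 1
        assert len(parts.inter) == 2

    @given(st.integers(0, 6))
    def test_pair_conservation(self, seed):
        """intra + inter + skipped covers every unordered pair exactly once."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        seqs = random_sequences(rng, n, 30, missing_prob=0.4)
        species = {sid: f"G sp{i % 3}" for i, sid in enumerate(seqs)}
        ds = dataset_from(seqs, species)
        try:
            m = distance_matrix(ds)
        except ValueError:
            return
        parts = partition_distances(m, ds.specimens)
        assert parts.n_pairs == n * (n - 1) // 2


class TestSummarize:
    def test_k_is_rounded_mean_substitutions(self):
        ds = dataset_from(
            {"x": "A" * 100, "y": "G" * 4 + "A" * 96},
            {"x": "G x", "y": "G y"},
        )
        s = summarize(
            distance_matrix(ds), distance_matrix(ds, "raw_substitutions"),
            ds.specimens, 100,
        )
        assert s.K == 4

    def test_rounding_half_up(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(2.49) == 2

    def test_single_species_has_no_inter_fields(self):
        ds = dataset_from(
            {"a": "AAAA", "b": "AATA"}, {"a": "G x", "b": "G x"}
        )
        s = summarize(
            distance_matrix(ds), distance_matrix(ds, "raw_substitutions"),
            ds.specimens, 4,
        )
        assert s.inter_mean is None
        assert s.intra_mean is not None

    def test_no_conspecific_pair_leaves_intra_absent(self):
        ds = dataset_from(
            {"a": "AAAA", "b": "AATA"}, {"a": "G x", "b": "G y"}
        )
        s = summarize(
            distance_matrix(ds), distance_matrix(ds, "raw_substitutions"),
            ds.specimens, 4,
        )
        assert s.intra_mean is None
        assert s.inter_range is not None
        assert s.inter_range[0] <= s.inter_mean <= s.inter_range[1]

    def test_simulated_intra_matches_truth(self, small_sim):
        """Mean intraspecific distance tracks the generator's parameter."""
        from barcodeval.io_alignments import single_marker_dataset

        ds = single_marker_dataset(small_sim.alignments["mA"], small_sim.specimens)
        m = distance_matrix(ds)
        parts = partition_distances(m, ds.specimens)
        truth = small_sim.params.intraspecific_depth
        assert parts.intra.mean() == pytest.approx(truth, abs=3 * truth)
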