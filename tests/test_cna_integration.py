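import itertools

import numpy as np
import pytest

from paradoxcna import cna_integration as cna
from paradoxcna.formats_io import MISSING_CALL, GenomicInterval


def dataset(probes, calls, prefix="s"):
    calls = np.asarray(calls, dtype=np.int8)
    return cna.ProbeCallDataset(
        probes=[GenomicInterval("chr1", s, e, f"p{i}")
                for i, (s, e) in enumerate(probes)],
        sample_ids=[f"{prefix}{j}" for j in range(calls.shape[1])],
        calls=calls)


class TestThresholdCaller:
    def test_neutral_gain_and_boundary(self):
        values = np.array([[0.0, 0.3, -0.2, 0.2, -0.5, np.nan]])
        calls = cna.call_from_log_ratios(values, -0.2, 0.2)
        # strict inequalities: exactly +/-0.2 stays neutral
        np.testing.assert_array_equal(
            calls[0], [0, 1, 0, 0, -1, MISSING_CALL])

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            cna.call_from_log_ratios(np.zeros((1, 1)), 0.2, 0.2)
        with pytest.raises(ValueError):
            cna.call_from_log_ratios(np.zeros((1, 1)), -np.inf, 0.2)


class TestAnchorTable:
    def test_single_probe_half_open_coverage(self):
        ds = dataset([(10, 20)], [[1]])
        table = cna.build_anchor_table([ds])
        # anchors at both boundaries; position 20 is outside the probe
        assert list(table.positions) == [10, 20]
        assert table.n_informative[0] == 1 and table.n_informative[1] == 0

    def test_anchor_missing_from_two_of_three_datasets_dropped(self):
        d1 = dataset([(0, 10)], [[1]])
        d2 = dataset([(0, 10)], [[1]])
        d3 = dataset([(0, 10), (50, 60)], [[1], [1]])
        table = cna.build_anchor_table([d1, d2, d3])
        # anchors 50/60 covered by at most one dataset -> dropped; end
        # boundaries (10, 60) are covered by nobody (half-open) -> dropped
        assert set(table.positions) == {0}

    def test_two_overlapping_grids_hand_enumeration(self):
        d1 = dataset([(0, 10)], [[1]])
        d2 = dataset([(5, 15)], [[1]], prefix="t")
        table = cna.build_anchor_table([d1, d2])
        # anchors {0,5,10,15}; 15 is uncovered by both -> dropped
        assert list(table.positions) == [0, 5, 10]
        i = list(table.positions).index(5)
        assert table.n_informative[i] == 2
        assert table.gain_freq[i] == 1.0

    def test_disjoint_chromosomes_rejected(self):
        d1 = dataset([(0, 10)], [[1]])
        d2 = cna.ProbeCallDataset(
            probes=[GenomicInterval("chr9", 0, 10, "p")],
            sample_ids=["s0"], calls=np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError, match="disjoint"):
            cna.build_anchor_table([d1, d2])

    def test_smaller_span_probe_wins(self):
        ds = dataset([(0, 100), (40, 60)], [[1], [-1]])
        table = cna.build_anchor_table([ds])
        i = list(table.positions).index(40)
        assert table.loss_count[i] == 1 and table.gain_count[i] == 0

    def test_identical_grids_equal_sample_concatenation(self):
        rng = np.random.default_rng(5)
        probes = [(i * 10, (i + 1) * 10) for i in range(20)]
        c1 = rng.choice([-1, 0, 1], size=(20, 7))
        c2 = rng.choice([-1, 0, 1], size=(20, 4))
        separate = cna.build_anchor_table([dataset(probes, c1),
                                           dataset(probes, c2, prefix="t")])
        merged = cna.build_anchor_table([dataset(probes, np.hstack([c1, c2]))])
        # compare on the anchors retained by both (the trailing boundary is
        # uncovered, so the two-dataset table drops it)
        common = np.isin(merged.positions, separate.positions)
        np.testing.assert_array_equal(separate.gain_count, merged.gain_count[common])
        np.testing.assert_array_equal(separate.loss_count, merged.loss_count[common])
        np.testing.assert_array_equal(separate.n_informative,
                                      merged.n_informative[common])

    def test_counts_never_exceed_informative(self):
        rng = np.random.default_rng(6)
        ds = [dataset([(i * 7, i * 7 + 9) for i in range(15)],
                      rng.choice([-1, 0, 1], size=(15, 5)), prefix=f"d{k}")
              for k in range(2)]
        table = cna.build_anchor_table(ds)
        assert (table.gain_count + table.loss_count <= table.n_informative).all()


def exhaustive_null_tail(calls, observed_gain):
    """Exact P(gain count at each anchor >= observed) by enumerating every
    per-sample permutation of its calls across anchors."""
    n_anchors, n_samples = calls.shape
    perms = [list(itertools.permutations(calls[:, s])) for s in range(n_samples)]
    total, hits = 0, np.zeros(n_anchors)
    for combo in itertools.product(*perms):
        mat = np.array(combo).T
        total += 1
        hits += (mat == 1).sum(axis=1) >= observed_gain
    return hits / total


class TestFrequencyTest:
    def test_all_neutral_gives_p_one(self):
        ds = dataset([(0, 10), (10, 20)], np.zeros((2, 3)))
        table = cna.build_anchor_table([ds])
        p_gain, p_loss = cna.anchor_frequency_test(table, n_perm=200, seed=0)
        assert (p_gain == 1.0).all() and (p_loss == 1.0).all()

    def test_minimum_attainable_p(self):
        # every sample gained at anchor 0, but only at 10% of its anchors:
        # no permutation can beat the observed all-samples count
        n_anchors, n_samples = 40, 10
        calls = np.zeros((n_anchors, n_samples), dtype=np.int8)
        calls[0, :] = 1
        for s in range(n_samples):
            calls[1 + 3 * s:1 + 3 * s + 3, s] = 1   # 4 gains of 40 anchors
        probes = [(i * 10, (i + 1) * 10) for i in range(n_anchors - 1)]
        ds = dataset(probes, calls[:-1])            # boundaries give 40 anchors
        table = cna.build_anchor_table([ds])
        p_gain, _ = cna.anchor_frequency_test(table, n_perm=999, seed=1)
        assert p_gain[0] == pytest.approx(1 / 1000)

    def test_matches_exhaustive_toy_enumeration(self):
        # 3 samples x 4 anchors; exact null by brute-force permutation
        calls = np.array([[1, 1, 0],
                          [1, 0, 0],
                          [0, 0, 1]], dtype=np.int8)
        probes = [(0, 10), (10, 20), (20, 30)]
        ds = dataset(probes, calls)
        table = cna.build_anchor_table([ds])
        # all samples are informative exactly at the three probe anchors
        exact = exhaustive_null_tail(calls, table.gain_count[:3])
        n_perm = 40_000
        p_gain, _ = cna.anchor_frequency_test(table, n_perm=n_perm, seed=2)
        for i in range(3):
            expected = (exact[i] * n_perm + 1) / (n_perm + 1)
            mc_sd = np.sqrt(exact[i] * (1 - exact[i]) / n_perm)
            assert abs(p_gain[i] - expected) <= 3 * mc_sd + 1e-9

    def test_p_stable_when_doubling_permutations(self):
        rng = np.random.default_rng(3)
        ds = dataset([(i * 10, (i + 1) * 10) for i in range(10)],
                     rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1], size=(10, 12)))
        table = cna.build_anchor_table([ds])
        p1, _ = cna.anchor_frequency_test(table, n_perm=4000, seed=4)
        p2, _ = cna.anchor_frequency_test(table, n_perm=8000, seed=5)
        mc_sd = np.sqrt(np.maximum(p1 * (1 - p1), 0.25 / 4000) / 4000)
        assert (np.abs(p1 - p2) <= 2 * mc_sd + 2 / 4000).all()

    def test_rejects_zero_permutations(self):
        ds = dataset([(0, 10)], [[1]])
        table = cna.build_anchor_table([ds])
        with pytest.raises(ValueError):
            cna.anchor_frequency_test(table, n_perm=0)


def make_table(positions, p_gain, p_loss, gain_freq=None, loss_freq=None):
    n = len(positions)
    calls = np.zeros((n, 1), dtype=np.int8)
    table = cna.AnchorTable(
        chroms=np.array(["chr1"] * n, dtype=object),
        positions=np.asarray(positions), calls=calls,
        sample_ids=["s0"], sample_dataset=np.zeros(1, dtype=int))
    table.p_gain = np.asarray(p_gain, dtype=float)
    table.p_loss = np.asarray(p_loss, dtype=float)
    if gain_freq is not None:
        table.gain_count = np.asarray(gain_freq)
        table.loss_count = np.asarray(loss_freq)
        table.n_informative = np.ones(n, dtype=int)
    return table


class TestRegionMerging:
    def test_no_significant_anchors(self):
        table = make_table([0, 100], [1.0, 1.0], [1.0, 1.0])
        assert cna.merge_significant_anchors(table) == []

    def test_adjacent_significant_gains_merge(self):
        table = make_table([0, 100], [0.01, 0.01], [1.0, 1.0])
        regions = cna.merge_significant_anchors(table)
        assert len(regions) == 1
        r = regions[0]
        assert r.direction == 1
        assert (r.interval.start, r.interval.end) == (0, 101)

    def test_loss_anchor_splits_gain_run(self):
        table = make_table([0, 100, 200, 300, 400],
                           [0.01, 0.01, 1.0, 0.01, 0.01],
                           [1.0, 1.0, 0.01, 1.0, 1.0])
        regions = cna.merge_significant_anchors(table)
        assert [r.direction for r in regions] == [1, -1, 1]
        assert len([r for r in regions if r.direction == 1]) == 2

    def test_large_gap_splits_run(self):
        table = make_table([0, 2_000_000], [0.01, 0.01], [1.0, 1.0])
        regions = cna.merge_significant_anchors(table, max_gap=500_000)
        assert len(regions) == 2
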