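import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from libscal import intervals as iv
from libscal import simulate as sim
from libscal.dataset import SpectralDataset
from libscal.preprocess import split_rank_ordered

# Published 28-interval removal ledger for the full 22,015-channel axis:
# removal order and the channel count each step's model used.
REMOVAL_ORDER_28 = [
    1, 4, 28, 20, 5, 3, 12, 27, 7, 26, 2, 6, 13, 14,
    25, 21, 18, 23, 24, 22, 16, 17, 19, 15, 9, 8, 11, 10,
]
COUNTS_28 = [
    22015, 21228, 20441, 19655, 18869, 18082, 17295, 16509, 15723, 14936,
    14150, 13363, 12576, 11790, 11004, 10218, 9432, 8646, 7860, 7074,
    6288, 5502, 4716, 3930, 3144, 2358, 1572, 786,
]


class TestPartition:
    def test_28_intervals_of_full_axis(self):
        part = iv.partition_equidistant(22015, 28)
        assert part.sizes[:7] == (787,) * 7
        assert part.sizes[7:] == (786,) * 21

    def test_eighth_of_thirteen_has_1693_channels(self):
        part = iv.partition_equidistant(22015, 13)
        assert part.sizes[7] == 1693

    def test_remainder_first_convention(self):
        assert iv.partition_equidistant(10, 3).sizes == (4, 3, 3)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            iv.partition_equidistant(10, 0)
        with pytest.raises(ValueError):
            iv.partition_equidistant(10, 11)

    @given(st.integers(1, 5000), st.integers(1, 60))
    def test_partition_properties(self, p, k):
        if k > p:
            p, k = k, p
        part = iv.partition_equidistant(p, k)
        sizes = part.sizes
        assert sum(sizes) == p
        assert max(sizes) - min(sizes) <= 1
        assert sorted(sizes, reverse=True) == list(sizes)
        # contiguous cover
        assert part.boundaries[0][0] == 0 and part.boundaries[-1][1] == p
        for (s1, e1), (s2, e2) in zip(part.boundaries, part.boundaries[1:]):
            assert e1 == s2

    def test_replay_counts_match_published_ledger(self):
        part = iv.partition_equidistant(22015, 28)
        assert part.replay_counts(REMOVAL_ORDER_28) == COUNTS_28

    def test_replay_requires_permutation(self):
        part = iv.partition_equidistant(100, 4)
        with pytest.raises(ValueError):
            part.replay_counts([1, 2, 2, 4])


def _affine_dataset(n=12, p=9, seed=0):
    rng = np.random.default_rng(seed)
    w = np.linspace(300, 400, p)
    cd = rng.uniform(0, 10, n)
    X = rng.normal(0, 1, (n, p))
    X[:, 4] = 2.0 * cd + 1.0  # one perfectly informative channel
    return SpectralDataset(w, X, cd, [f"s{i}" for i in range(n)])


class TestIntervalScore:
    def test_exact_affine_relation_scores_zero(self):
        d = _affine_dataset()
        score, lv = iv.interval_score(d, [4], max_lv=1)
        assert score < 1e-6 and lv == 1

    def test_constant_channels_equal_mean_predictor(self):
        # closed form on a 5-sample toy: LOO prediction is the mean of the
        # other four, so the error is 5/4 of the deviation from the mean.
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        d = SpectralDataset(
            np.linspace(1, 3, 3), np.ones((5, 3)), y, list("abcde")
        )
        expected = np.sqrt(np.mean((5.0 / 4.0 * (y - y.mean())) ** 2))
        score, _ = iv.interval_score(d, [0, 1, 2], max_lv=1)
        assert score == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_channel_ordering(self):
        d = _affine_dataset(seed=2)
        a, _ = iv.interval_score(d, [2, 4, 6], max_lv=3)
        b, _ = iv.interval_score(d, [6, 2, 4], max_lv=3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_max_lv_bound_enforced(self):
        d = _affine_dataset(n=6)
        with pytest.raises(ValueError):
            iv.interval_score(d, [0, 1], max_lv=3)  # bound is min(n-2, 2)


@pytest.fixture(scope="module")
def cal_data():
    cfg = sim.small_config(
        n_channels=1500, replicates=2, shot_sigma=0.0, matrix_trend=0.0, seed=21
    )
    d = sim.simulate_dataset(cfg)
    return d.take(split_rank_ordered(d.reference).calibration)


class TestIplsSelect:
    def test_selects_interval_containing_strongest_line(self, cal_data):
        sel = iv.ipls_select(cal_data, range(4, 13), max_lv=4)
        assert cal_data.nearest_channel(508.58) in sel.channels

    def test_k_range_of_one_returns_full_spectrum(self, cal_data):
        sel = iv.ipls_select(cal_data, [1], max_lv=4)
        assert sel.channels.size == cal_data.p

    def test_scale_invariant(self, cal_data):
        scaled = SpectralDataset(
            cal_data.wavelengths,
            cal_data.intensities * 10.0,
            cal_data.reference,
            cal_data.ids,
        )
        a = iv.ipls_select(cal_data, [6], max_lv=3)
        b = iv.ipls_select(scaled, [6], max_lv=3)
        assert np.array_equal(a.channels, b.channels)

    def test_ranges_consistent_with_channels(self, cal_data):
        sel = iv.ipls_select(cal_data, [8], max_lv=3)
        lo, hi = sel.ranges[0]
        w = cal_data.wavelengths[sel.channels]
        assert lo == w[0] and hi == w[-1]

    def test_empty_k_range_rejected(self, cal_data):
        with pytest.raises(ValueError):
            iv.ipls_select(cal_data, [], max_lv=3)


class TestBiplsEliminate:
    def test_two_intervals_single_elimination(self, cal_data):
        ledger = iv.bipls_eliminate(cal_data, 2, max_lv=3)
        assert len(ledger.steps) == 2
        first, last = ledger.steps
        assert first.n_intervals == 2 and last.n_intervals == 1
        # the survivor is whichever alone scores lower
        part = ledger.partition
        scores = [
            iv.interval_score(cal_data, part.channels(i), 3)[0] for i in range(2)
        ]
        assert last.remaining[0] - 1 == int(np.argmin(scores))

    def test_counts_decrease_by_removed_interval_size(self, cal_data):
        ledger = iv.bipls_eliminate(cal_data, 6, max_lv=3)
        sizes = ledger.partition.sizes
        counts = ledger.remaining_counts
        for prev, nxt, step in zip(counts, counts[1:], ledger.steps):
            assert prev - nxt == sizes[step.removed - 1]
        assert counts[0] == cal_data.p

    def test_frame_mirrors_ledger_columns(self, cal_data):
        frame = iv.bipls_eliminate(cal_data, 4, max_lv=3).to_frame()
        assert list(frame.columns) == [
            "n_intervals", "removed_interval", "rmsecv", "n_lv", "n_channels",
        ]
        assert list(frame.n_intervals) == [4, 3, 2, 1]


class TestBiplsSelect:
    def test_informative_interval_always_retained(self, cal_data):
        sel = iv.bipls_select(cal_data, [5, 9], max_lv=3)
        assert cal_data.nearest_channel(508.58) in sel.channels

    def test_channel_count_equals_sum_of_interval_sizes(self, cal_data):
        sel = iv.bipls_select(cal_data, [7], max_lv=3)
        part = iv.partition_equidistant(cal_data.p, 7)
        retained = [
            i for i in range(7)
            if np.isin(part.channels(i), sel.channels).all()
        ]
        assert sel.channels.size == sum(part.sizes[i] for i in retained)

    def test_ranges_map_through_axis(self, cal_data):
        sel = iv.bipls_select(cal_data, [7], max_lv=3)
        covered = np.concatenate([
            np.flatnonzero(
                (cal_data.wavelengths >= lo) & (cal_data.wavelengths <= hi)
            )
            for lo, hi in sel.ranges
        ])
        assert np.array_equal(np.sort(covered), sel.channels)


class TestSelectionFile:
    def test_roundtrip(self, cal_data, tmp_path):
        sel = iv.ipls_select(cal_data, [6], max_lv=3)
        path = tmp_path / "sel.txt"
        iv.write_selection(sel, path)
        assert np.array_equal(iv.read_selection(path), sel.channels)
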