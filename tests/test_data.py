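import collections

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ocrdenovo.data import (
    LabeledDataset,
    build_dataset,
    filter_peaks,
    kfold_split,
    make_positive_windows,
    one_hot_decode,
    one_hot_encode,
    shuffle_negative,
    split_dataset,
)
from ocrdenovo.io import GenomicInterval, SequenceRecord


def _genome(length=1000, seed=0):
    rng = np.random.default_rng(seed)
    return [SequenceRecord("c1", "".join(rng.choice(list("ACGT"), size=length)))]


class TestFilterPeaks:
    def test_boundary_is_strict(self):
        peaks = [GenomicInterval("c1", 0, n) for n in (150, 200, 201, 300)]
        assert [p.length for p in filter_peaks(peaks, 200)] == [201, 300]

    def test_all_filtered_warns(self):
        with pytest.warns(UserWarning, match="no peaks"):
            assert filter_peaks([GenomicInterval("c1", 0, 50)], 200) == []


class TestPositiveWindows:
    def test_center_window_coordinates(self):
        g = _genome()
        (iv, seq), = make_positive_windows(g, [GenomicInterval("c1", 100, 400)], 36)
        assert (iv.start, iv.end) == (232, 268)
        assert seq == g[0].seq[232:268]

    def test_center_count_preserved(self):
        g = _genome()
        peaks = [GenomicInterval("c1", s, s + 250) for s in (0, 300, 700)]
        assert len(make_positive_windows(g, peaks, 36)) == 3

    def test_clipped_window_dropped_with_warning(self):
        g = [SequenceRecord("c1", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")]
        with pytest.warns(UserWarning, match="dropped"):
            out = make_positive_windows(g, [GenomicInterval("c1", 0, 10)], 36)
        assert out == []

    def test_tile_mode_covers_peak(self):
        g = _genome()
        peak = GenomicInterval("c1", 100, 220)
        out = make_positive_windows(g, [peak], 36, mode="tile")
        assert [w[0].start for w in out] == [100, 136, 172]
        assert all(w[0].length == 36 for w in out)

    def test_window_longer_than_chromosome(self):
        with pytest.raises(ValueError):
            make_positive_windows(_genome(20), [GenomicInterval("c1", 0, 10)], 36)


class TestShuffleNegative:
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300), st.integers(0, 2**31 - 1))
    def test_letter_counts_conserved(self, seq, seed):
        assert collections.Counter(shuffle_negative(seq, seed)) == collections.Counter(seq)

    def test_single_letter_multiset(self):
        assert shuffle_negative("AAAA", 3) == "AAAA"

    def test_seed_determinism(self):
        assert shuffle_negative("ACGTACGTACGT", 5) == shuffle_negative("ACGTACGTACGT", 5)
        outs = {shuffle_negative("ACGTACGTACGT", s) for s in range(20)}
        assert len(outs) > 1


class TestOneHot:
    def test_acgt_is_identity(self):
        assert np.array_equal(one_hot_encode("ACGT"), np.eye(4))

    def test_n_is_zero_column(self):
        assert np.array_equal(one_hot_encode("N"), np.zeros((4, 1)))

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=100))
    def test_round_trip(self, seq):
        assert one_hot_decode(one_hot_encode(seq)) == seq

    def test_illegal_symbol(self):
        with pytest.raises(ValueError, match="'X'"):
            one_hot_encode("ACXT")


def _pairs(n, length=8):
    rng = np.random.default_rng(0)
    ids, seqs, labels, pids = [], [], [], []
    for k in range(n):
        s = "".join(rng.choice(list("ACGT"), size=length))
        for tag, lab in (("pos", 1), ("neg", 0)):
            ids.append(f"{tag}{k}")
            seqs.append(s)
            labels.append(lab)
            pids.append(k)
    return LabeledDataset(ids, seqs, np.array(labels), ["train"] * 2 * n,
                          np.array(pids), length)


class TestSplit:
    def test_ten_pairs_split_6_2_2(self):
        ds = split_dataset(_pairs(10), seed=1)
        sizes = {p: len(ds.subset(p)) // 2 for p in ("train", "validation", "test")}
        assert sizes == {"train": 6, "validation": 2, "test": 2}

    def test_partitions_disjoint_union_and_balanced(self):
        ds = split_dataset(_pairs(57), seed=2)
        total = 0
        for p in ("train", "validation", "test"):
            sub = ds.subset(p)
            total += len(sub)
            assert (sub.labels == 1).sum() == (sub.labels == 0).sum()
        assert total == len(ds)

    def test_determinism(self):
        a = split_dataset(_pairs(40), seed=9)
        b = split_dataset(_pairs(40), seed=9)
        assert a.partitions == b.partitions

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            split_dataset(_pairs(4))


class TestKFold:
    def test_even_folds(self):
        folds = kfold_split(_pairs(100), k=10, seed=0)
        assert all(len(test) // 2 == 10 for _, test in folds)

    def test_remainder_fold_sizes(self):
        folds = kfold_split(_pairs(23), k=10, seed=0)
        sizes = sorted(len(test) // 2 for _, test in folds)
        assert sizes == [2, 2, 2, 2, 2, 2, 2, 3, 3, 3]

    def test_test_folds_cover_everything_once(self):
        ds = _pairs(23)
        folds = kfold_split(ds, k=10, seed=3)
        seen = [i for _, test in folds for i in test.ids]
        assert sorted(seen) == sorted(ds.ids)
        for train, test in folds:
            assert set(train.ids).isdisjoint(test.ids)
            assert len(train) + len(test) == len(ds)

    def test_k_larger_than_n(self):
        with pytest.raises(ValueError):
            kfold_split(_pairs(5), k=10)


class TestBuildDataset:
    def test_balance_composition_and_determinism(self, tmp_path):
        genome = _genome(5000, seed=3)
        peaks = [GenomicInterval("c1", s, s + 250) for s in range(100, 4500, 450)]
        ds = build_dataset(genome, peaks, fragment_length=120, seed=5)
        assert (ds.labels == 1).sum() == (ds.labels == 0).sum()
        by_pair = {}
        for i, pid in enumerate(ds.pair_ids):
            by_pair.setdefault(int(pid), []).append(i)
        for idx in by_pair.values():
            a, b = (ds.sequences[i] for i in idx)
            assert collections.Counter(a) == collections.Counter(b)
        ds2 = build_dataset(genome, peaks, fragment_length=120, seed=5)
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        ds.to_tsv(p1)
        ds2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tsv_round_trip(self, tmp_path):
        genome = _genome(5000, seed=3)
        peaks = [GenomicInterval("c1", s, s + 250) for s in range(100, 4500, 450)]
        ds = build_dataset(genome, peaks, fragment_length=60, seed=5)
        p = tmp_path / "ds.tsv"
        ds.to_tsv(p)
        back = LabeledDataset.from_tsv(p)
        assert back.sequences == ds.sequences
        assert back.partitions == ds.partitions
        assert np.array_equal(back.labels, ds.labels)
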