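"""Training-set construction from a genome and an accessibility peak BED.

The pipeline mirrors how open-chromatin classifiers are usually trained:
peaks longer than 200 bp are kept as positives (long fragments carry more
statistical power), a fixed-width window is cut from each peak, each
positive is letter-shuffled into a composition-matched negative, and the
balanced set is split 60/20/20 into train/validation/test.  A positive and
the negative derived from it always land in the same partition, so a
shuffled copy can never leak across the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, SequenceRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PARTITIONS = ("train", "validation", "test")


def filter_peaks(
    peaks: list[GenomicInterval], min_length: int = 200
) -> list[GenomicInterval]:
    """Keep peaks strictly longer than ``min_length`` bp, in input order."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [p for p in peaks if p.length > min_length]
    if peaks and not kept:
        warnings.warn(
            f"no peaks longer than {min_length} bp; positive set is empty",
            stacklevel=2,
        )
    return kept


def make_positive_windows(
    genome: list[SequenceRecord] | dict[str, str],
    peaks: list[GenomicInterval],
    length: int,
    mode: str = "center",
) -> list[tuple[GenomicInterval, str]]:
    """Cut fixed-width sequence windows from (already filtered) peaks.

    mode="center": one ``length``-bp window centered on each peak midpoint;
    windows that would run off the chromosome are dropped with a warning.
    mode="tile": non-overlapping ``length``-bp windows covering each peak
    (the final partial window is dropped).

    Returns (window interval, uppercase sequence) pairs.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if mode not in ("center", "tile"):
        raise ValueError(f"unknown mode {mode!r}")
    seqs = genome if isinstance(genome, dict) else {r.id: r.seq for r in genome}
    for chrom, seq in seqs.items():
        if length > len(seq):
            raise ValueError(
                f"window length {length} exceeds chromosome {chrom!r} "
                f"length {len(seq)}"
            )
    out: list[tuple[GenomicInterval, str]] = []
    n_dropped = 0
    for peak in peaks:
        chrom_len = len(seqs[peak.chrom])
        if mode == "center":
            mid = (peak.start + peak.end) // 2
            start = mid - length // 2
            end = start + length
            if start < 0 or end > chrom_len:
                n_dropped += 1
                continue
            iv = GenomicInterval(peak.chrom, start, end)
            out.append((iv, seqs[peak.chrom][start:end].upper()))
        else:
            for s in range(peak.start, peak.end - length + 1, length):
                iv = GenomicInterval(peak.chrom, s, s + length)
                out.append((iv, seqs[peak.chrom][s : s + length].upper()))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} peak(s) whose centered window overlapped a "
            "chromosome end",
            stacklevel=2,
        )
    return out


def shuffle_negative(seq: str, seed: int) -> str:
    """Permute the letters of ``seq`` (deterministic for a fixed seed).

    The returned string has exactly the per-letter counts of the input
    (including N), which is the point: a negative that matches its positive
    in base composition but has no intact motifs.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    return "".join(rng.permutation(letters))


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a 4 x n binary matrix (rows A, C, G, T).

    N encodes as an all-zero column.
    """
    n = len(seq)
    m = np.zeros((4, n), dtype=np.float64)
    for j, base in enumerate(seq.upper()):
        if base == "N":
            continue
        try:
            m[_BASE_INDEX[base], j] = 1.0
        except KeyError:
            raise ValueError(f"illegal symbol {base!r} at position {j}") from None
    return m


def one_hot_decode(m: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero columns decode to N."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != 4:
        raise ValueError("expected a 4 x n matrix")
    out = []
    for j in range(m.shape[1]):
        col = m[:, j]
        nz = np.flatnonzero(col)
        if nz.size == 0:
            out.append("N")
        elif nz.size == 1 and col[nz[0]] == 1.0:
            out.append(BASES[nz[0]])
        else:
            raise ValueError(f"column {j} is not a valid one-hot column: {col}")
    return "".join(out)


@dataclass
class LabeledDataset:
    """Balanced, encoded fragments with train/validation/test tags.

    Rows come in (positive, shuffled-negative) pairs; ``pair_id`` links them
    and both members always carry the same partition tag.
    """

    ids: list[str]
    sequences: list[str]
    labels: np.ndarray  # int, {0, 1}
    partitions: list[str]
    pair_ids: np.ndarray  # int, pair index
    fragment_length: int
    intervals: list[GenomicInterval | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.sequences) == len(self.labels) == len(self.partitions) == n):
            raise ValueError("field lengths disagree")
        if any(len(s) != self.fragment_length for s in self.sequences):
            raise ValueError("all fragments must have fragment_length")
        if not self.intervals:
            self.intervals = [None] * n

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        return len(self.ids) // 2

    def subset(self, partition: str) -> "LabeledDataset":
        idx = [i for i, p in enumerate(self.partitions) if p == partition]
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            partitions=[self.partitions[i] for i in idx],
            pair_ids=self.pair_ids[idx],
            fragment_length=self.fragment_length,
            intervals=[self.intervals[i] for i in idx],
        )

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y): X is (n, 4, fragment_length), y is (n,)."""
        X = np.stack([one_hot_encode(s) for s in self.sequences])
        return X, self.labels.astype(np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "label": self.labels,
                "partition": self.partitions,
                "pair_id": self.pair_ids,
                "sequence": self.sequences,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
        seqs = df["sequence"].tolist()
        if not seqs:
            raise ValueError(f"dataset file {path} is empty")
        return cls(
            ids=df["id"].tolist(),
            sequences=seqs,
            labels=df["label"].to_numpy(dtype=int),
            partitions=df["partition"].tolist(),
            pair_ids=df["pair_id"].to_numpy(dtype=int),
            fragment_length=len(seqs[0]),
        )


def build_dataset(
    genome: list[SequenceRecord] | dict[str, str],
    peaks: list[GenomicInterval],
    fragment_length: int,
    seed: int,
    min_peak_length: int = 200,
    mode: str = "center",
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
) -> LabeledDataset:
    """Full dataset construction: filter, window, shuffle negatives, split."""
    kept = filter_peaks(peaks, min_peak_length)
    windows = make_positive_windows(genome, kept, fragment_length, mode)
    if not windows:
        raise ValueError("no positive windows could be constructed")
    ss = np.random.SeedSequence(seed)
    shuffle_seeds = ss.generate_state(len(windows) + 1)
    ids, seqs, labels, pair_ids, intervals = [], [], [], [], []
    for k, (iv, pos_seq) in enumerate(windows):
        neg_seq = shuffle_negative(pos_seq, int(shuffle_seeds[k]) % 2**31)
        ids.append(f"pos_{k}")
        seqs.append(pos_seq)
        labels.append(1)
        pair_ids.append(k)
        intervals.append(iv)
        ids.append(f"neg_{k}")
        seqs.append(neg_seq)
        labels.append(0)
        pair_ids.append(k)
        intervals.append(None)
    ds = LabeledDataset(
        ids=ids,
        sequences=seqs,
        labels=np.array(labels),
        partitions=["train"] * len(ids),
        pair_ids=np.array(pair_ids),
        fragment_length=fragment_length,
        intervals=intervals,
    )
    return split_dataset(ds, fractions, seed=int(shuffle_seeds[-1]) % 2**31)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n items to fractions by the largest-remainder rule."""
    raw = [n * f for f in fractions]
    sizes = [int(x) for x in raw]
    remainders = [x - s for x, s in zip(raw, sizes)]
    for i in sorted(range(len(fractions)), key=lambda i: -remainders[i])[
        : n - sum(sizes)
    ]:
        sizes[i] += 1
    return sizes


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
) -> LabeledDataset:
    """Seed-deterministic random partition of pairs into train/val/test.

    Pairs (a positive and its shuffled negative) stay together, so every
    partition remains exactly class-balanced.  Sizes follow the
    largest-remainder rounding of the requested fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pairs = np.unique(ds.pair_ids)
    if pairs.size < 5:
        raise ValueError("need at least 5 pairs to honor a 3-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pairs)
    sizes = _largest_remainder(pairs.size, fractions)
    assignment: dict[int, str] = {}
    cursor = 0
    for part, size in zip(PARTITIONS, sizes):
        for pid in order[cursor : cursor + size]:
            assignment[int(pid)] = part
        cursor += size
    partitions = [assignment[int(pid)] for pid in ds.pair_ids]
    return LabeledDataset(
        ids=ds.ids,
        sequences=ds.sequences,
        labels=ds.labels,
        partitions=partitions,
        pair_ids=ds.pair_ids,
        fragment_length=ds.fragment_length,
        intervals=ds.intervals,
    )


def kfold_split(ds: LabeledDataset, k: int = 10, seed: int = 0):
    """Yield k (train, test) LabeledDataset pairs over shuffled pairs.

    Fold sizes differ by at most one pair and every sample appears in
    exactly one test fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pairs = np.unique(ds.pair_ids)
    if k > pairs.size:
        raise ValueError(f"k={k} exceeds number of pairs {pairs.size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pairs)
    folds = np.array_split(order, k)
    out = []
    for fold in folds:
        test_set = set(int(p) for p in fold)
        test_idx = [i for i, p in enumerate(ds.pair_ids) if int(p) in test_set]
        train_idx = [i for i, p in enumerate(ds.pair_ids) if int(p) not in test_set]

        def take(idx):
            return LabeledDataset(
                ids=[ds.ids[i] for i in idx],
                sequences=[ds.sequences[i] for i in idx],
                labels=ds.labels[idx],
                partitions=[ds.partitions[i] for i in idx],
                pair_ids=ds.pair_ids[idx],
                fragment_length=ds.fragment_length,
                intervals=[ds.intervals[i] for i in idx],
            )

        out.append((take(train_idx), take(test_idx)))
    return out
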