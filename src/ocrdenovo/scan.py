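"""De novo genome scanning: windows -> probabilities -> per-base scores -> peaks.

The genome is split into fixed-width windows taken every ``step`` bases
(36 bp windows every 5 bp is the classical geometry for this task; when a
trained model is supplied the window width is its input length).  Window
probabilities are projected to per-base scores by taking, at every base,
the maximum probability over the windows covering it, and maximal runs of
bases at or above a threshold become called peaks after gap merging and a
minimum-length filter — a deliberately simple stand-in for an external
peak caller, with an export path for users who prefer one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import one_hot_encode
from .io import GenomicInterval, SequenceRecord, write_bed
from .nn import CNNModel, predict_proba

DEFAULT_WINDOW = 36
DEFAULT_STEP = 5

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ProbabilityTrack:
    """Per-window open-chromatin probabilities along one chromosome."""

    chrom: str
    window_starts: np.ndarray
    window_width: int
    step: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.window_starts.shape != self.probs.shape:
            raise ValueError("window_starts and probs must align")
        if self.window_starts.size > 1:
            diffs = np.diff(self.window_starts)
            if not np.all(diffs == self.step):
                raise ValueError("window starts must increase by step")


@dataclass
class PeakCall:
    """A called peak: interval, summit offset, and maximal probability."""

    interval: GenomicInterval
    summit: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.summit < self.interval.length):
            raise ValueError("summit must lie within the peak")


def sliding_windows(
    seq_length: int, width: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> np.ndarray:
    """Start coordinates 0, step, 2*step, ... with start+width <= seq_length.

    Incomplete tail windows are dropped; a sequence shorter than one window
    yields no starts (with a warning).
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    if seq_length < width:
        warnings.warn(
            f"sequence length {seq_length} shorter than window width {width}; "
            "no windows emitted",
            stacklevel=2,
        )
        return np.empty(0, dtype=np.int64)
    return np.arange(0, seq_length - width + 1, step, dtype=np.int64)


def score_genome(
    model: CNNModel,
    genome: list[SequenceRecord],
    step: int = DEFAULT_STEP,
    batch_size: int = 512,
    both_strands: bool = False,
) -> list[ProbabilityTrack]:
    """Score every window of every chromosome with the trained classifier.

    The window width is the model's input length.  With ``both_strands``
    each window also scores its reverse complement and keeps the per-window
    maximum.  Chromosomes shorter than one window are skipped with a
    warning.
    """
    width = model.spec.input_length
    tracks: list[ProbabilityTrack] = []
    for rec in genome:
        if len(rec.seq) < width:
            warnings.warn(
                f"chromosome {rec.id!r} shorter than window width {width}; skipped",
                stacklevel=2,
            )
            continue
        starts = sliding_windows(len(rec.seq), width, step)
        onehot = one_hot_encode(rec.seq)  # (4, L)
        probs = np.empty(starts.size)
        for lo in range(0, starts.size, batch_size):
            batch_starts = starts[lo : lo + batch_size]
            X = np.stack([onehot[:, s : s + width] for s in batch_starts])
            p = predict_proba(model, X)
            if both_strands:
                p = np.maximum(p, predict_proba(model, X[:, ::-1, ::-1]))
            probs[lo : lo + p.size] = p
        tracks.append(
            ProbabilityTrack(
                chrom=rec.id,
                window_starts=starts,
                window_width=width,
                step=step,
                probs=probs,
            )
        )
    return tracks


def track_to_basescores(
    track: ProbabilityTrack, chrom_length: int, aggregate: str = "max"
) -> np.ndarray:
    """Project window probabilities to per-base scores.

    aggregate="max": score(b) = max over covering windows (default;
    preserves peak sharpness at small steps).  aggregate="mean" averages
    instead.  Bases covered by no window score 0.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    scores = np.zeros(chrom_length)
    w = track.window_width
    if aggregate == "max":
        for s, p in zip(track.window_starts, track.probs):
            seg = scores[s : s + w]
            np.maximum(seg, p, out=seg)
    else:
        total = np.zeros(chrom_length)
        count = np.zeros(chrom_length)
        for s, p in zip(track.window_starts, track.probs):
            total[s : s + w] += p
            count[s : s + w] += 1
        covered = count > 0
        scores[covered] = total[covered] / count[covered]
    return scores


def call_peaks(
    basescores: np.ndarray,
    chrom: str,
    threshold: float = 0.5,
    merge_gap: int = 50,
    min_length: int = DEFAULT_WINDOW,
) -> list[PeakCall]:
    """Threshold-merge peak calling on a per-base score array.

    Maximal runs of bases with score >= threshold are found; runs separated
    by fewer than ``merge_gap`` sub-threshold bases are merged; merged runs
    shorter than ``min_length`` are discarded.  The summit is the leftmost
    base attaining the run's maximal score.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    basescores = np.asarray(basescores, dtype=np.float64)
    above = basescores >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    run_starts = list(np.flatnonzero(edges == 1) + 1)
    run_ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        run_starts.insert(0, 0)
    if above[-1]:
        run_ends.append(len(above))

    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks: list[PeakCall] = []
    for s, e in merged:
        if e - s < min_length:
            continue
        seg = basescores[s:e]
        summit = int(np.argmax(seg))
        peaks.append(
            PeakCall(
                interval=GenomicInterval(chrom, s, e, score=float(seg[summit])),
                summit=summit,
                score=float(seg[summit]),
            )
        )
    return peaks


def peaks_to_bed(peaks: list[PeakCall], path) -> None:
    """Write called peaks as BED6; the score is max probability x1000."""
    with open(path, "w") as fh:
        for k, pk in enumerate(peaks, start=1):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tOCR_{k}\t"
                f"{round(pk.score * 1000)}\t.\n"
            )


def export_fragments_for_external_caller(
    tracks: list[ProbabilityTrack] | ProbabilityTrack, threshold: float, path
) -> None:
    """Write windows with probability >= threshold as BED6, sorted.

    This preserves the route of handing thresholded windows to an external
    peak caller instead of the built-in threshold-merge caller.
    """
    if isinstance(tracks, ProbabilityTrack):
        tracks = [tracks]
    rows: list[GenomicInterval] = []
    for tr in tracks:
        keep = tr.probs >= threshold
        for s, p in zip(tr.window_starts[keep], tr.probs[keep]):
            rows.append(
                GenomicInterval(
                    tr.chrom, int(s), int(s) + tr.window_width, score=float(p)
                )
            )
    rows.sort(key=lambda iv: (iv.chrom, iv.start))
    write_bed(rows, path, columns=6)


def write_bedgraph(basescores: np.ndarray, chrom: str, path, mode: str = "w") -> None:
    """Append per-base scores as bedGraph runs of constant value (zeros skipped)."""
    vals = np.asarray(basescores)
    change = np.r_[0, np.flatnonzero(np.diff(vals) != 0) + 1, len(vals)]
    with open(path, mode) as fh:
        for lo, hi in zip(change[:-1], change[1:]):
            v = vals[lo]
            if v > 0:
                fh.write(f"{chrom}\t{lo}\t{hi}\t{v:.6f}\n")
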