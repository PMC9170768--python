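"""Motif extraction from trained first-layer convolution filters.

A first-layer filter behaves as a motif prober: positions in the positive
set where its raw activation exceeds a fraction of the filter's maximal
activation are harvested, the aligned subsequences are stacked into a
position frequency matrix (PFM), and the PFM is converted into a
probability matrix with per-column information content in bits (0 for a
uniform column, 2 for a fixed base) — the quantities a sequence logo draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BASES, one_hot_decode
from .nn import CNNModel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PFM:
    """Position frequency matrix: per-position base counts (rows A,C,G,T)."""

    counts: np.ndarray  # (4, w) non-negative ints
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWM:
    """Column-stochastic base probabilities with information content in bits."""

    probs: np.ndarray  # (4, w), columns sum to 1
    name: str = "motif"
    n_sites: int = 0
    ic: np.ndarray = field(init=False)
    logo_heights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x w matrix")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        self.ic = column_information_content(self.probs)
        self.logo_heights = self.probs * self.ic

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), name=self.name + "_rc",
                   n_sites=self.n_sites)


def column_information_content(probs: np.ndarray) -> np.ndarray:
    """ic_j = 2 + sum_b p log2 p, per column; 0 bits uniform, 2 bits fixed."""
    p = np.asarray(probs, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def harvest_activations(
    model: CNNModel,
    positives: np.ndarray,
    threshold_frac: float = 0.5,
    min_hits: int = 10,
    batch_size: int = 256,
) -> tuple[dict[int, list[str]], set[int]]:
    """Collect, per filter, the subsequences driving strong activations.

    For each first-layer filter, every position in the positive set whose
    raw (pre-ReLU) activation exceeds ``threshold_frac`` times that
    filter's maximum over the whole positive set contributes its aligned
    filter-width subsequence.  Subsequences containing N are skipped.
    Filters with fewer than ``min_hits`` surviving hits are flagged
    inactive.

    Returns (subsequences per filter index, set of inactive filter indices).
    """
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must be in (0, 1]")
    if not model.trained:
        raise ValueError("model has not been trained")
    X = np.asarray(positives, dtype=np.float64)
    w = model.spec.conv1_width
    n_filters = model.spec.conv1_filters

    # pass 1: per-filter maxima over all positives and positions
    maxima = np.full(n_filters, -np.inf)
    for start in range(0, X.shape[0], batch_size):
        acts = model.conv1_preactivations(X[start : start + batch_size])
        maxima = np.maximum(maxima, acts.max(axis=(0, 1)))

    subseqs: dict[int, list[str]] = {f: [] for f in range(n_filters)}
    for start in range(0, X.shape[0], batch_size):
        batch = X[start : start + batch_size]
        acts = model.conv1_preactivations(batch)  # (n, L1, F)
        for f in range(n_filters):
            if maxima[f] <= 0:
                continue
            hit_n, hit_pos = np.nonzero(acts[:, :, f] > threshold_frac * maxima[f])
            for i, pos in zip(hit_n, hit_pos):
                window = batch[i, :, pos : pos + w]
                if window.sum() < w:  # contains at least one N column
                    continue
                subseqs[f].append(one_hot_decode(window))
    inactive = {f for f in range(n_filters) if len(subseqs[f]) < min_hits}
    return subseqs, inactive


def build_pfm(subsequences: list[str]) -> PFM:
    """Stack equal-width subsequences into per-position base counts."""
    if not subsequences:
        raise ValueError("need at least one subsequence")
    w = len(subsequences[0])
    if any(len(s) != w for s in subsequences):
        raise ValueError("subsequences must share one width")
    counts = np.zeros((4, w), dtype=np.int64)
    for s in subsequences:
        for j, base in enumerate(s):
            counts[BASES.index(base), j] += 1
    return PFM(counts=counts, n_sites=len(subsequences))


def pfm_to_pwm(pfm: PFM, pseudocount: float = 0.25, name: str = "motif") -> PWM:
    """Pseudocounted probabilities: (count + pc) / (n_sites + 4 pc)."""
    if pfm.n_sites < 1:
        raise ValueError("PFM has no sites")
    probs = (pfm.counts + pseudocount) / (pfm.n_sites + 4.0 * pseudocount)
    return PWM(probs=probs, name=name, n_sites=pfm.n_sites)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 4):
    """Best ungapped alignment of two PWMs by column-wise Pearson correlation.

    All offsets with >= ``min_overlap`` overlapping columns are scored in
    both orientations (b is also reverse-complemented); the correlation is
    computed over the flattened 4 x overlap probability block.

    Returns (score in [-1, 1], offset of b relative to a, orientation).
    """
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError(f"both PWMs need width >= {min_overlap}")
    best = (-np.inf, 0, "+")
    for orient, bb in (("+", b), ("-", b.reverse_complement())):
        for offset in range(-(bb.width - min_overlap), a.width - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(a.width, offset + bb.width)
            if a_hi - a_lo < min_overlap:
                continue
            b_lo = a_lo - offset
            score = _pearson(
                a.probs[:, a_lo:a_hi].ravel(),
                bb.probs[:, b_lo : b_lo + (a_hi - a_lo)].ravel(),
            )
            if score > best[0]:
                best = (score, offset, orient)
    return best


def consensus(pwm: PWM) -> str:
    """Highest-probability base at each column."""
    return "".join(BASES[i] for i in pwm.probs.argmax(axis=0))


# -- MEME minimal motif format -------------------------------------------

def write_meme(pwms: list[PWM], path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    for p in pwms:
        if not np.allclose(p.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"motif {p.name!r} has non-stochastic columns")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background)
        )
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {max(p.n_sites, 1)} E= 0\n"
            )
            for j in range(p.width):
                fh.write(
                    " ".join(f"{p.probs[i, j]:.6f}" for i in range(4)) + "\n"
                )
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    """Read the minimal-MEME subset written by :func:`write_meme`.

    Also accepts JASPAR-style MEME exports that follow the same layout.
    """
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    expect_w = None

    def flush():
        nonlocal name, rows, expect_w
        if name is not None and rows:
            probs = np.asarray(rows).T  # rows are positions -> (4, w)
            probs = probs / probs.sum(axis=0, keepdims=True)
            pwms.append(PWM(probs=probs, name=name, n_sites=nsites[0]))
        name, rows, expect_w = None, [], None

    nsites = [0]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
                nsites[0] = 0
            elif line.startswith("letter-probability matrix"):
                for tok_key, tok_val in zip(line.split(), line.split()[1:]):
                    if tok_key == "w=":
                        expect_w = int(tok_val)
                    if tok_key == "nsites=":
                        nsites[0] = int(tok_val)
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(t) for t in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
    flush()
    return pwms


def write_logo_heights(pwm: PWM, path) -> None:
    """Per-position logo letter heights (probability x information content)."""
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tic_bits\n")
        for j in range(pwm.width):
            heights = "\t".join(f"{pwm.logo_heights[i, j]:.6f}" for i in range(4))
            fh.write(f"{j}\t{heights}\t{pwm.ic[j]:.6f}\n")
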