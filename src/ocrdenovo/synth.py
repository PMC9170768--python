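"""Synthetic genomes with planted motifs and ground-truth open regions.

The generator emulates the premise that accessibility assays reveal only
part of a genome's open chromatin: it writes a background genome, plants
motif instances inside non-overlapping "true" OCR intervals, and then
subsamples those intervals at a detection rate to produce the "observed"
peak set a training pipeline would actually get from an assay.  Everything
is seed-deterministic, down to the output bytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenomicInterval, SequenceRecord, write_bed, write_fasta
from .motifs import PWM

BASES = np.array(list("ACGT"))


def _ic_of_p(p: float) -> float:
    """Information content of a (p, q, q, q) column, q = (1-p)/3."""
    q = (1.0 - p) / 3.0
    terms = [p] + [q] * 3
    return 2.0 + sum(t * np.log2(t) for t in terms if t > 0)


def sample_motif(width: int, target_ic_per_col: float, seed: int = 0) -> PWM:
    """Random PWM whose mean per-column information content hits a target.

    Each column puts probability p on a randomly chosen dominant base and
    (1-p)/3 on the rest, with p solved by bisection so the column carries
    exactly ``target_ic_per_col`` bits.
    """
    if not (4 <= width <= 30):
        raise ValueError("width must be in [4, 30]")
    if not (0.0 <= target_ic_per_col <= 2.0):
        raise ValueError("target information content must be in [0, 2] bits")
    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(80):  # bisection: ic is increasing in p on [0.25, 1)
        mid = 0.5 * (lo + hi)
        if _ic_of_p(mid) < target_ic_per_col:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    q = (1.0 - p) / 3.0
    rng = np.random.default_rng(seed)
    probs = np.full((4, width), q)
    for j in range(width):
        probs[rng.integers(0, 4), j] = p
    probs /= probs.sum(axis=0, keepdims=True)
    return PWM(probs=probs, name=f"planted_w{width}")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study."""

    genome_length: int = 500_000
    n_chroms: int = 1
    background_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_pwms: list[PWM] = field(default_factory=list)
    n_ocrs: int = 400
    ocr_length_mean: int = 250
    ocr_length_sd: int = 30
    ocr_min_length: int = 205  # keeps every OCR above the >200 bp peak filter
    motifs_per_ocr: int = 3
    assay_detection_rate: float = 0.8
    seed: int = 11

    def __post_init__(self) -> None:
        if abs(sum(self.background_base_probs) - 1.0) > 1e-9:
            raise ValueError("background base probabilities must sum to 1")
        if not (0.0 < self.assay_detection_rate <= 1.0):
            raise ValueError("assay_detection_rate must be in (0, 1]")


def default_scenario(seed: int = 11) -> SyntheticSpec:
    """The canonical desk-scale scenario.

    One 500 kb chromosome with uniform background, a single 12 bp planted
    motif at 1.6 bits per column, 400 non-overlapping OCRs of 250 +- 30 bp
    (all above the 200 bp training filter), 3 motif instances per OCR, and
    an assay that detects 80% of the true OCRs.
    """
    motif = sample_motif(12, 1.6, seed=seed * 7919 + 1)
    return SyntheticSpec(motif_pwms=[motif], seed=seed)


def _sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
    return "".join(BASES[c] for c in cols)


def _place_nonoverlapping(
    rng: np.random.Generator, region_length: int, lengths: list[int], max_tries: int
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    for ln in lengths:
        ok = False
        for _ in range(max_tries):
            start = int(rng.integers(0, region_length - ln + 1))
            if all(start + ln <= s or start >= e for s, e in placed):
                placed.append((start, start + ln))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place non-overlapping intervals; region too crowded"
            )
    return sorted(placed)


def build_genome(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[GenomicInterval], list[GenomicInterval]]:
    """Generate (genome records, truth OCR BED, observed assay BED).

    Background bases are drawn i.i.d. from ``background_base_probs``; each
    OCR receives ``motifs_per_ocr`` independent PWM draws at random
    non-overlapping offsets; the observed set is a seed-deterministic
    subsample of the truth at the assay detection rate.
    """
    if not spec.motif_pwms:
        raise ValueError("spec must provide at least one motif PWM")
    footprint = spec.n_ocrs * (spec.ocr_length_mean + 3 * spec.ocr_length_sd)
    if footprint >= 0.5 * spec.genome_length:
        raise ValueError("total OCR footprint must stay below 50% of the genome")
    rng = np.random.default_rng(spec.seed)

    # chromosome lengths: genome length split evenly
    base = spec.genome_length // spec.n_chroms
    chrom_lengths = [base] * spec.n_chroms
    chrom_lengths[-1] += spec.genome_length - base * spec.n_chroms

    # OCR counts per chromosome, proportional to length
    counts = [round(spec.n_ocrs * ln / spec.genome_length) for ln in chrom_lengths]
    counts[-1] += spec.n_ocrs - sum(counts)

    records: list[SequenceRecord] = []
    truth: list[GenomicInterval] = []
    for c, (chrom_len, n_here) in enumerate(zip(chrom_lengths, counts), start=1):
        chrom = f"chr{c}"
        seq = BASES[
            rng.choice(4, size=chrom_len, p=np.asarray(spec.background_base_probs))
        ]
        lengths = []
        while len(lengths) < n_here:
            ln = int(round(rng.normal(spec.ocr_length_mean, spec.ocr_length_sd)))
            if ln >= spec.ocr_min_length:
                lengths.append(ln)
        spans = _place_nonoverlapping(rng, chrom_len, lengths, max_tries=10_000)
        for s, e in spans:
            offsets = _place_nonoverlapping(
                rng,
                e - s,
                [pwm.width for pwm in (
                    spec.motif_pwms[int(rng.integers(0, len(spec.motif_pwms)))]
                    for _ in range(spec.motifs_per_ocr)
                )],
                max_tries=10_000,
            )
            # re-draw which pwm goes where so widths and draws stay aligned
            for off_s, off_e in offsets:
                candidates = [p for p in spec.motif_pwms if p.width == off_e - off_s]
                pwm = candidates[int(rng.integers(0, len(candidates)))]
                inst = _sample_from_pwm(pwm, rng)
                seq[s + off_s : s + off_e] = list(inst)
            truth.append(GenomicInterval(chrom, s, e))
        records.append(SequenceRecord(chrom, "".join(seq)))

    detected = rng.random(len(truth)) < spec.assay_detection_rate
    observed = [iv for iv, d in zip(truth, detected) if d]
    if not observed:
        warnings.warn("assay detected no OCRs at this rate/seed", stacklevel=2)
    return records, truth, observed


def materialize(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Write genome.fa, truth.bed, and observed.bed into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth, observed = build_genome(spec)
    paths = {
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.bed",
        "observed": outdir / "observed.bed",
    }
    write_fasta(records, paths["genome"])
    write_bed(truth, paths["truth"], columns=3)
    write_bed(observed, paths["observed"], columns=3)
    return paths
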