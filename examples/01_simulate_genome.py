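"""Generate a small synthetic genome with planted open chromatin regions.

The generator writes three artifacts: the genome FASTA, the ground-truth
OCR intervals, and the "observed" peak set — the subsample of the truth an
accessibility assay would have detected.  The gap between truth and
observed is the point of the exercise: the predictor is trained on the
observed peaks and judged on the full truth.
"""

import collections

from ocrdenovo import SyntheticSpec, build_genome, sample_motif

motif = sample_motif(width=12, target_ic_per_col=1.6, seed=77)
spec = SyntheticSpec(
    genome_length=120_000,
    n_ocrs=80,
    motif_pwms=[motif],
    assay_detection_rate=0.8,
    seed=5,
)
records, truth, observed = build_genome(spec)

counts = collections.Counter(records[0].seq)
total = len(records[0].seq)
print(f"genome: {len(records)} chromosome(s), {total:,} bp")
print("base composition:", {b: round(counts[b] / total, 3) for b in "ACGT"})
print(f"planted motif consensus-ish columns: {motif.ic.mean():.2f} bits/col")
print(f"true OCRs: {len(truth)} (lengths {min(iv.length for iv in truth)}-"
      f"{max(iv.length for iv in truth)} bp)")
print(f"observed by the simulated assay: {len(observed)} "
      f"({100 * len(observed) / len(truth):.0f}% detection)")
print()
print("The observed set is what a real DNase-/ATAC-seq experiment hands a")
print("training pipeline; the remaining OCRs exist but were not detected.")
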