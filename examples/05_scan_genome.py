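"""De novo prediction: scan a genome and call open chromatin regions.

Every window (the model's input width, every 5 bp) is scored with the
trained classifier; window probabilities are averaged into per-base
scores; runs of bases at or above 0.5 become peaks after gap merging.
Because the model was trained on only the *observed* ~80% of OCRs, recall
on the full truth set includes regions the simulated assay missed.

Run 03_train_classifier.py first; this example loads its artifacts.
"""

import sys
from pathlib import Path

import numpy as np

from ocrdenovo import (
    call_peaks, intersect, load_model, read_bed, read_fasta, score_genome,
    track_to_basescores,
)
from ocrdenovo.scan import peaks_to_bed

out = Path("ocrdenovo_example")
if not (out / "model.npz").exists():
    sys.exit("missing ./ocrdenovo_example/model.npz - run 03_train_classifier.py first")

model = load_model(out / "model.npz")
records = read_fasta(out / "genome.fa")
truth = read_bed(out / "truth.bed")
observed = read_bed(out / "observed.bed")

(track,) = score_genome(model, records, step=5)
print(f"scored {track.probs.size:,} windows of {track.window_width} bp (step {track.step})")

scores = track_to_basescores(track, len(records[0].seq), aggregate="mean")
peaks = call_peaks(scores, track.chrom, threshold=0.5, merge_gap=50, min_length=36)
peaks_to_bed(peaks, out / "predictions.bed")
print(f"called {len(peaks)} peaks -> ocrdenovo_example/predictions.bed")

hit = {(a.chrom, a.start, a.end)
       for a, _ in intersect(truth, [p.interval for p in peaks], 1)}
truth_mask = np.zeros(len(records[0].seq), dtype=bool)
for iv in truth:
    truth_mask[iv.start:iv.end] = True
called_mask = np.zeros_like(truth_mask)
for p in peaks:
    called_mask[p.interval.start:p.interval.end] = True

print(f"recall: {100 * len(hit) / len(truth):.1f}% of the {len(truth)} true OCRs "
      f"overlap a called peak")
print(f"precision: {100 * truth_mask[called_mask].mean():.1f}% of called bases "
      f"lie inside true OCRs")
print(f"(the model saw only {len(observed)} of {len(truth)} OCRs during training)")
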