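"""Read motifs out of the trained network's first-layer filters.

Positions in the positive set where a filter's activation exceeds half of
that filter's maximum contribute their aligned subsequences; stacking them
gives a PFM, pseudocounting a PWM with per-column information content.
The learned motifs are compared to the planted one by the best ungapped
Pearson alignment (both orientations), the same machinery one would use
against a JASPAR export.

Run 03_train_classifier.py first; this example loads its artifacts.
"""

import sys
from pathlib import Path

import numpy as np

from ocrdenovo import (
    LabeledDataset, build_pfm, harvest_activations, load_model,
    one_hot_encode, pfm_to_pwm, pwm_similarity, read_meme, write_meme,
)
from ocrdenovo.motifs import consensus

out = Path("ocrdenovo_example")
if not (out / "model.npz").exists():
    sys.exit("missing ./ocrdenovo_example/model.npz - run 03_train_classifier.py first")

model = load_model(out / "model.npz")
ds = LabeledDataset.from_tsv(out / "dataset.tsv")
planted = read_meme(out / "planted_motif.meme")[0]

positives = np.stack(
    [one_hot_encode(s) for s, l in zip(ds.sequences, ds.labels) if l == 1]
)
subseqs, inactive = harvest_activations(model, positives, threshold_frac=0.5)

pwms = []
for f, seqs in subseqs.items():
    if f not in inactive:
        pwms.append(pfm_to_pwm(build_pfm(seqs), name=f"filter_{f}"))
write_meme(pwms, out / "filters.meme")

scored = sorted(
    ((pwm_similarity(p, planted)[0], p) for p in pwms), key=lambda t: -t[0]
)
print(f"{len(pwms)} of {model.spec.conv1_filters} filters were active")
print(f"planted motif consensus: {consensus(planted)}")
print("top filter motifs by similarity to the planted motif:")
for score, pwm in scored[:3]:
    print(f"  {pwm.name:>10}: similarity {score:.3f}, "
          f"consensus {consensus(pwm)}, {pwm.n_sites} sites")
print()
print("similarity ~1.0 means a filter's probability matrix aligns almost")
print("perfectly with the motif planted in the open regions; all motifs")
print("were written to ocrdenovo_example/filters.meme (MEME minimal format).")
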