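# Methods

## Model and assumptions

`ocrdenovo` treats open-chromatin prediction as sequence classification:
the working assumption is that accessibility is driven by clusters of
short (6–19 bp) protein-binding motifs, so a model that can tell genuine
peak sequence from a base-composition-matched shuffle has, by
construction, learned motif content rather than nucleotide frequencies.
The classifier is a three-hidden-layer convolutional network — two
stride-1 valid convolutions and one 200-unit dense layer, each followed
by ReLU and inverted dropout, with a sigmoid output read as the
probability that the fragment lies in open chromatin. There is no
pooling: stride-1 convolutions keep the positional resolution that filter
→ motif conversion relies on.

Negatives are per-letter shuffles of the positives (one per positive), so
classes are exactly balanced and share base composition, including N
counts. A positive and its shuffle always occupy the same
train/validation/test partition; otherwise a near-copy of a training
sequence could leak into evaluation.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| peak filter `min_length` | 200 | bp | only peaks strictly longer are used; longer fragments carry more statistical power |
| fragment / input length | 120 | bp | see "Window-length trade-off" below |
| conv1 | 64 filters x 19 bp | — | width covers the 6–19 bp motif range; counts sized for desk-scale data, configurable |
| conv2 | 32 filters x 11 bp | — | combines low-level features; same three technologies (conv, ReLU, dropout) as layer 1 |
| dense units | 200 | — | the fully connected layer's fixed width |
| dropout p | 0.6 | — | applied after every hidden layer, inverted convention |
| optimizer | momentum SGD, lr 0.05, momentum 0.9, batch 32, 100 epochs, weight decay 1e-3 on weight matrices | — | see "Optimizer choice" |
| harvest `threshold_frac` | 0.5 | fraction of per-filter max activation | the established convention for filter-to-motif conversion in sequence CNNs |
| PWM pseudocount | 0.25 | counts/base | avoids log 0 with minimal distortion |
| scan window / step | model input length / 5 | bp | step 5 trades location accuracy against compute; the free-standing window geometry helper defaults to the classical 36 bp |
| peak calling | threshold 0.5, merge_gap 50, min_length 36 | probability / bp | 0.5 is the sigmoid decision point; 50 bp ≈ 10 steps smooths jitter; 36 bp = one classical window |

## Window-length trade-off

Training peaks are hundreds of bp, but the network needs one fixed input
width, which is also the scan width. Two failure modes bound the choice.
Too short (e.g. 36 bp): a window centered on a ~250 bp peak usually
misses every motif in it, so a large fraction of "positives" carry no
signal and held-out discrimination is capped near AUROC 0.7 regardless of
the model. Too long (≥ ~200 bp): every scan window overlapping a peak
edge still contains motifs, so called peaks smear far beyond the true
region and base-level precision collapses. 120 bp sits between the two:
~80% of centered windows contain at least one intact motif (ceiling
AUROC ≈ 0.9 under the synthetic scenario's geometry) while scan smearing
stays within what pileup averaging removes. Both `center` and `tile`
windowing modes are provided; `center` (one window per peak midpoint) is
the default, and windows that would cross a chromosome end are dropped,
not padded, because padding semantics for training sequence are
undefined.

## Optimizer choice

The flatten→dense layer holds ~590k of the ~617k parameters. At the
few-hundred-fragment scale of the synthetic benchmark, Adam (any tried
learning rate, dropout, or weight decay) drives that layer to memorize
the training set: training accuracy reaches 0.99 while held-out AUROC
stays at 0.5. Plain momentum SGD with a small L2 penalty instead finds
the solution that spreads a motif-filter's weight across positions —
effectively the position-invariant feature — and reaches held-out AUROC
≈ 0.91 with the default dropout of 0.6 left in place. SGD is
therefore the default; Adam remains available via `model.optimizer` and
is a reasonable choice at the tens-of-thousands-of-peaks scale of real
datasets.

## Scanning and peak calling

Window probabilities are projected to per-base scores before calling.
The op-level default aggregation is the max over covering windows; the
pipeline default is the mean. The difference matters for calling: with a
120 bp window every false-positive window under max aggregation stamps
120 bases at full score, and measured on the default scenario the ~2.7%
background windows above 0.5 pull base-level precision down to ~0.52.
Mean aggregation (each base is covered by ~window/step windows) suppresses
isolated false positives and trims peak edges, giving precision ~0.84 at
recall 1.0. Both are exposed as `scan.aggregate`.

The built-in caller is deliberately simple — threshold, merge gaps
shorter than `merge_gap`, drop runs shorter than `min_length`, summit at
the leftmost maximal base — because external callers' fragment-pileup
models are not what this package contributes. Users who want the
external-caller route can export thresholded windows as BED
(`scan.write_fragments`) and feed them to their caller of choice.
Scoring the reverse complement and taking the per-window max is available
(`scan.both_strands`) but off by default; planted-motif benchmarks are
single-stranded and OCR calls are strand-agnostic.

## Synthetic benchmark

The generator emulates the core epistemic situation of accessibility
mapping: a genome whose true OCR set is known, and an assay that reports
only a fraction of it. Background bases are i.i.d. from a configurable
composition (uniform by default); non-overlapping OCR intervals
(250 ± 30 bp, all above the 200 bp filter) receive a fixed number of
motif instances sampled from a planted PWM at random non-overlapping
offsets; the observed peak set is a Bernoulli subsample of the truth at
the assay detection rate (0.8 by default). The default scenario is one
500 kb chromosome, 400 OCRs, one 12 bp motif at 1.6 bits/column, three
instances per OCR.

What the generator does *not* model: nuclease/transposase sequence bias,
read-level noise and fragment-size structure, GC heterogeneity, repeats,
multiple cooperating motif families, strand effects, and peak-caller
boundary error (observed peaks equal true intervals exactly). Passing the
end-to-end benchmark therefore shows that the pipeline's machinery —
encoding, training, motif read-out, scanning, calling — recovers planted
structure through an assay-incompleteness bottleneck; it does not certify
performance on real genomes, where signal is weaker and backgrounds are
structured.

Problem sizes throughout the test suite and the acceptance script (500 kb
genome, ~320 observed peaks, 100 epochs) are the package's chosen
desk-scale defaults; every knob scales up through the config.

## Numerical choices

- Probabilities are clipped at ε = 1e-7 inside the cross-entropy; the
  sigmoid uses the two-branch form to avoid overflow.
- He-normal initialization, seed-deterministic; training, shuffling and
  dropout draw from one seeded generator, so a (spec, dataset) pair
  reproduces byte-identical results run to run.
- Model selection: weights from the epoch with minimal validation loss
  (the validation partition exists; using it for selection is the
  conventional reading).
- Convolutions are im2col matrix products; gradients are exact
  (verified against central differences in the test suite).
- Split sizes follow largest-remainder rounding; k-fold folds differ by
  at most one pair.
- Filter-motif harvesting thresholds raw pre-ReLU scores (equivalent to
  post-ReLU for the positive thresholds that occur in practice);
  subsequences containing N are skipped (an N column carries no
  frequency information); filters with fewer than 10 hits are flagged
  inactive. All-zero filters never exceed the threshold.
- PWM-PWM similarity is Pearson correlation on probability columns over
  all ungapped offsets with ≥ 4 overlapping columns, both orientations;
  probabilities rather than log-odds keep near-uniform columns
  well-behaved.
- Motif-free degenerate inputs: IUPAC ambiguity codes are mapped to N
  with a warning (the encoding alphabet has exactly five symbols);
  lowercase (soft-masked) bases are uppercased and used, since repeat
  masking is not part of the model.
- Chromosomes shorter than one window are skipped with a warning;
  all-N windows produce a constant probability (a property test).

## Known limitations

- Position-specific dense weights need either pooling-free weight
  spreading (SGD + L2, small data) or large sample counts; very small
  peak sets (≲ 150 pairs) may need more epochs (`model.epochs`) to leave
  the memorization regime.
- One fixed input width serves training and scanning; genomes whose
  regulatory regions differ greatly in scale from the training peaks
  would need retraining at a different `model.input_length`.
- The internal caller has no background model; on real data with
  structured background the exported-fragments + external-caller route
  is likely preferable.
- FASTA/BED I/O is plain-text only (no bgzip/2bit/indexed access), and
  genome scanning is single-threaded numpy: throughput is roughly a few
  hundred kb of genome per minute at the default architecture.
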