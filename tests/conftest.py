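import json

import numpy as np
import pytest
from hypothesis import settings

from ocrdenovo import intersect, pipeline, read_bed, read_meme
from ocrdenovo.motifs import pwm_similarity

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def e2e_chain(tmp_path_factory):
    """Full default-scenario pipeline run: simulate -> ... -> predict.

    Returns the output directory plus the headline quantities (held-out
    AUROC, best filter-motif similarity, OCR recall, base-level precision)
    computed from the written artifacts.
    """
    outdir = tmp_path_factory.mktemp("e2e")
    cfg = pipeline.PipelineConfig()
    cfg.paths.outdir = str(outdir)
    pipeline.run_all(cfg)

    with open(outdir / "test_metrics.json") as fh:
        test_metrics = json.load(fh)

    planted = read_meme(outdir / "planted_motif.meme")[0]
    learned = read_meme(outdir / "motifs.meme")
    best_sim = max(pwm_similarity(pwm, planted)[0] for pwm in learned)

    truth = read_bed(outdir / "truth.bed")
    predicted = read_bed(outdir / "predictions.bed")
    hit = {
        (a.chrom, a.start, a.end) for a, _ in intersect(truth, predicted, 1)
    }
    recall = len(hit) / len(truth)

    genome_length = cfg.simulate.genome_length
    truth_mask = np.zeros(genome_length, dtype=bool)
    for iv in truth:
        truth_mask[iv.start : iv.end] = True
    called_mask = np.zeros(genome_length, dtype=bool)
    for iv in predicted:
        called_mask[iv.start : iv.end] = True
    precision = float(truth_mask[called_mask].mean()) if called_mask.any() else 0.0

    return {
        "outdir": outdir,
        "config": cfg,
        "auroc": test_metrics["auroc"],
        "auprc": test_metrics["auprc"],
        "n_test": test_metrics["n_test"],
        "best_motif_similarity": best_sim,
        "n_motifs": len(learned),
        "ocr_recall": recall,
        "base_precision": precision,
        "n_predicted": len(predicted),
    }
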