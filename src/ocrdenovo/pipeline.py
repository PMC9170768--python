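"""Pipeline stages behind the command line: simulate -> preprocess -> train
-> motif -> predict.

Each stage reads its inputs from, and writes its artifacts into, one output
directory, logs parameters and record counts, and is idempotent: rerunning
with the same config and seeds reproduces the same bytes.  A structured
YAML config with schema validation (unknown keys rejected) carries every
tunable; every field has a documented default.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import data as _data
from . import io as _io
from . import metrics as _metrics
from . import motifs as _motifs
from . import nn as _nn
from . import scan as _scan
from . import synth as _synth

log = logging.getLogger("ocrdenovo")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PathsConfig(_Section):
    genome: str | None = None  # reference genome FASTA
    peaks: str | None = None  # accessibility peak BED (training input)
    outdir: str = "ocrdenovo_out"


class DatasetConfig(_Section):
    min_peak_length: int = 200  # keep peaks strictly longer than this
    mode: Literal["center", "tile"] = "center"
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0


class ModelConfig(_Section):
    conv1_filters: int = 64
    conv1_width: int = 19
    conv2_filters: int = 32
    conv2_width: int = 11
    fc_units: int = 200
    dropout_p: float = 0.6
    input_length: int = 120  # training fragment length = scan window width
    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 100
    optimizer: Literal["sgd", "adam"] = "sgd"
    momentum: float = 0.9
    weight_decay: float = 1e-3
    seed: int = 0

    def to_spec(self) -> _nn.ModelSpec:
        return _nn.ModelSpec(**self.model_dump())


class MotifConfig(_Section):
    threshold_frac: float = 0.5  # fraction of per-filter max activation
    pseudocount: float = 0.25
    min_sites: int = 10


class ScanConfig(_Section):
    step: int = 5
    threshold: float = 0.5
    merge_gap: int = 50
    min_length: int = 36
    # mean = coverage-style pileup averaging over the ~width/step windows
    # covering each base; robust to isolated false-positive windows, which
    # under "max" each stamp a full window width of called bases.
    aggregate: Literal["max", "mean"] = "mean"
    both_strands: bool = False
    write_fragments: bool = False
    write_bedgraph: bool = False


class SimulateConfig(_Section):
    genome_length: int = 500_000
    n_chroms: int = 1
    n_ocrs: int = 400
    ocr_length_mean: int = 250
    ocr_length_sd: int = 30
    motifs_per_ocr: int = 3
    motif_width: int = 12
    motif_ic: float = 1.6
    assay_detection_rate: float = 0.8
    seed: int = 11


class PipelineConfig(_Section):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    motif: MotifConfig = Field(default_factory=MotifConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    verbosity: Literal["debug", "info", "warning"] = "info"

    @property
    def outdir(self) -> Path:
        return Path(self.paths.outdir)

    def dump_effective(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def load_config(path=None, overrides: list[str] | None = None) -> PipelineConfig:
    """Load YAML config (defaults when path is None) and apply overrides.

    Overrides are dotted assignments, e.g. ``model.epochs=10``; values are
    parsed as YAML scalars.  Validation errors list every offending key.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    for ov in overrides or []:
        key, _, value = ov.partition("=")
        if not _:
            raise ValueError(f"override {ov!r} must look like section.key=value")
        node = raw
        parts = key.strip().split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(value)
    return PipelineConfig(**raw)


def _setup_logging(config: PipelineConfig) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    log.setLevel(getattr(logging, config.verbosity.upper()))
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (config.outdir / "run.log").resolve()
        for h in log.handlers
    ):
        handler = logging.FileHandler(config.outdir / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    config.dump_effective(config.outdir / "config_used.yaml")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {producer!r} stage first"
        )
    return path


def _genome_path(config: PipelineConfig) -> Path:
    if config.paths.genome:
        return Path(config.paths.genome)
    return _require(config.outdir / "genome.fa", "simulate")


def _peaks_path(config: PipelineConfig) -> Path:
    if config.paths.peaks:
        return Path(config.paths.peaks)
    return _require(config.outdir / "observed.bed", "simulate")


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Materialize a synthetic genome + truth/observed peak sets."""
    _setup_logging(config)
    sim = config.simulate
    motif = _synth.sample_motif(sim.motif_width, sim.motif_ic, seed=sim.seed * 7919 + 1)
    spec = _synth.SyntheticSpec(
        genome_length=sim.genome_length,
        n_chroms=sim.n_chroms,
        motif_pwms=[motif],
        n_ocrs=sim.n_ocrs,
        ocr_length_mean=sim.ocr_length_mean,
        ocr_length_sd=sim.ocr_length_sd,
        motifs_per_ocr=sim.motifs_per_ocr,
        assay_detection_rate=sim.assay_detection_rate,
        seed=sim.seed,
    )
    paths = _synth.materialize(spec, config.outdir)
    _motifs.write_meme([motif], config.outdir / "planted_motif.meme")
    truth = _io.read_bed(paths["truth"])
    observed = _io.read_bed(paths["observed"])
    log.info(
        "simulate: genome %d bp, %d true OCRs, %d observed peaks",
        sim.genome_length, len(truth), len(observed),
    )
    return paths


def run_preprocess(config: PipelineConfig) -> Path:
    """Genome + peaks -> balanced, split, serialized dataset TSV."""
    _setup_logging(config)
    genome = _io.read_fasta(_genome_path(config))
    peaks = _io.read_bed(_peaks_path(config))
    ds = _data.build_dataset(
        genome,
        peaks,
        fragment_length=config.model.input_length,
        seed=config.dataset.seed,
        min_peak_length=config.dataset.min_peak_length,
        mode=config.dataset.mode,
        fractions=config.dataset.fractions,
    )
    out = config.outdir / "dataset.tsv"
    ds.to_tsv(out)
    # FASTA export for interoperability with external motif tools
    pos = [_io.SequenceRecord(i, s) for i, s, l in zip(ds.ids, ds.sequences, ds.labels) if l == 1]
    neg = [_io.SequenceRecord(i, s) for i, s, l in zip(ds.ids, ds.sequences, ds.labels) if l == 0]
    _io.write_fasta(pos, config.outdir / "positives.fa")
    _io.write_fasta(neg, config.outdir / "negatives.fa")
    counts = {p: ds.partitions.count(p) for p in _data.PARTITIONS}
    log.info(
        "preprocess: %d peaks -> %d fragments (%s)", len(peaks), len(ds), counts
    )
    return out


def run_train(config: PipelineConfig) -> Path:
    """Train the classifier; write checkpoint, history, and test metrics."""
    _setup_logging(config)
    ds_path = _require(config.outdir / "dataset.tsv", "preprocess")
    ds = _data.LabeledDataset.from_tsv(ds_path)
    spec = config.model.to_spec()
    model = _nn.train_model(spec, ds)
    ckpt = config.outdir / "model.npz"
    _nn.save_model(model, ckpt)
    with open(config.outdir / "history.tsv", "w") as fh:
        fh.write("epoch\ttrain_loss\ttrain_acc\tval_loss\tval_acc\n")
        hist = model.history
        for e in range(len(hist["train_loss"])):
            fh.write(
                f"{e}\t{hist['train_loss'][e]:.6f}\t{hist['train_acc'][e]:.6f}"
                f"\t{hist['val_loss'][e]:.6f}\t{hist['val_acc'][e]:.6f}\n"
            )
    test = ds.subset("test")
    Xte, yte = test.encoded()
    probs = _nn.predict_proba(model, Xte)
    _, auroc = _metrics.roc_auroc(probs, yte)
    _, auprc = _metrics.pr_auprc(probs, yte)
    _metrics.write_roc_tsv(probs, yte, config.outdir / "test_roc.tsv")
    _metrics.write_pr_tsv(probs, yte, config.outdir / "test_pr.tsv")
    with open(config.outdir / "test_metrics.json", "w") as fh:
        json.dump({"auroc": auroc, "auprc": auprc, "n_test": len(yte)}, fh, indent=2)
    log.info("train: %d epochs, test AUROC %.4f AUPRC %.4f", spec.epochs, auroc, auprc)
    return ckpt


def run_motif(config: PipelineConfig) -> Path:
    """Convert first-layer filters to PFM/PWM motifs; write MEME + logos."""
    _setup_logging(config)
    ckpt = _require(config.outdir / "model.npz", "train")
    ds_path = _require(config.outdir / "dataset.tsv", "preprocess")
    model = _nn.load_model(ckpt)
    ds = _data.LabeledDataset.from_tsv(ds_path)
    pos_seqs = [s for s, l in zip(ds.sequences, ds.labels) if l == 1]
    X = np.stack([_data.one_hot_encode(s) for s in pos_seqs])
    subseqs, inactive = _motifs.harvest_activations(
        model, X, threshold_frac=config.motif.threshold_frac,
        min_hits=config.motif.min_sites,
    )
    pwms = []
    for f, seqs in subseqs.items():
        if f in inactive:
            continue
        pfm = _motifs.build_pfm(seqs)
        pwms.append(
            _motifs.pfm_to_pwm(pfm, config.motif.pseudocount, name=f"filter_{f}")
        )
    out = config.outdir / "motifs.meme"
    _motifs.write_meme(pwms, out)
    logo_dir = config.outdir / "logos"
    logo_dir.mkdir(exist_ok=True)
    for pwm in pwms:
        _motifs.write_logo_heights(pwm, logo_dir / f"{pwm.name}.tsv")
    log.info(
        "motif: %d/%d filters active, %d motifs written",
        len(pwms), model.spec.conv1_filters, len(pwms),
    )
    return out


def run_predict(config: PipelineConfig) -> Path:
    """Scan the genome with the trained model and emit predicted OCRs."""
    _setup_logging(config)
    ckpt = _require(config.outdir / "model.npz", "train")
    model = _nn.load_model(ckpt)
    genome = _io.read_fasta(_genome_path(config))
    tracks = _scan.score_genome(
        model, genome, step=config.scan.step, both_strands=config.scan.both_strands
    )
    chrom_lengths = {rec.id: len(rec.seq) for rec in genome}
    all_peaks: list[_scan.PeakCall] = []
    bedgraph = config.outdir / "scores.bedgraph"
    if config.scan.write_bedgraph and bedgraph.exists():
        bedgraph.unlink()
    for track in tracks:
        scores = _scan.track_to_basescores(
            track, chrom_lengths[track.chrom], aggregate=config.scan.aggregate
        )
        all_peaks.extend(
            _scan.call_peaks(
                scores,
                track.chrom,
                threshold=config.scan.threshold,
                merge_gap=config.scan.merge_gap,
                min_length=config.scan.min_length,
            )
        )
        if config.scan.write_bedgraph:
            _scan.write_bedgraph(scores, track.chrom, bedgraph, mode="a")
    out = config.outdir / "predictions.bed"
    _scan.peaks_to_bed(all_peaks, out)
    if config.scan.write_fragments:
        _scan.export_fragments_for_external_caller(
            tracks, config.scan.threshold, config.outdir / "fragments.bed"
        )
    n_windows = sum(t.probs.size for t in tracks)
    log.info("predict: %d windows scored, %d peaks called", n_windows, len(all_peaks))
    return out


def run_all(config: PipelineConfig) -> Path:
    """simulate (when no external inputs are configured) through predict."""
    if config.paths.genome is None or config.paths.peaks is None:
        run_simulate(config)
    run_preprocess(config)
    run_train(config)
    run_motif(config)
    return run_predict(config)
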