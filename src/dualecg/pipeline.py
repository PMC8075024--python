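"""End-to-end pipeline: denoise -> segment -> spectral features -> train ->
evaluate, with one config object and one seed governing every stage."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classes import CLASS_TO_INDEX
from .denoise import denoise as denoise_signal
from .network import ModelConfig, build_owcnn
from .segmenter import fit_standardizer, segment_record
from .spectral import spectral_matrix
from .trainer import Dataset, TrainConfig, class_weights, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run (fully serializable)."""

    # denoising
    denoise_enabled: bool = True
    denoise_wavelet: str = "db6"
    denoise_levels: int = 9
    zero_approx: bool = True
    zero_details: tuple[int, ...] = (1, 2)
    # segmentation
    segmentation_mode: str = "spanning"
    # model / training
    model: ModelConfig = field(default_factory=ModelConfig)
    eta0: float = 0.01
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    use_class_weights: bool = True
    # protocol
    protocol: str = "inter_patient"
    n_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def train_config(self, seed: int, weights=None) -> TrainConfig:
        return TrainConfig(
            eta0=self.eta0, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            seed=seed, class_weights=weights,
        )


def prepare_dataset(records, cfg: PipelineConfig | None = None) -> Dataset:
    """Denoise, segment and featurize a list of annotated records.

    Returns the aligned (inputs1, inputs2, labels, groups) dataset,
    **unstandardized** — standardization statistics must come from training
    folds only, so it is applied in :func:`train_fold`.
    """
    cfg = cfg or PipelineConfig()
    segs_all, labels, groups = [], [], []
    crop_stats = []
    for rec in records:
        signal = (
            denoise_signal(rec.samples, rec.fs, zero_approx=cfg.zero_approx,
                           zero_detail_levels=set(cfg.zero_details),
                           wavelet=cfg.denoise_wavelet, levels=cfg.denoise_levels)
            if cfg.denoise_enabled else rec.samples
        )
        segments, stats = segment_record(rec, signal, mode=cfg.segmentation_mode,
                                         with_stats=True)
        crop_stats.append(stats)
        for s in segments:
            segs_all.append(s.samples)
            labels.append(CLASS_TO_INDEX[s.label])
            groups.append(s.record_id)
    if not segs_all:
        raise ValueError("no segments produced: all beats excluded or skipped")
    n_emitted = sum(s.n_emitted for s in crop_stats)
    n_cropped = sum(s.n_cropped for s in crop_stats)
    logger.info("prepared %d segments from %d records (crop rate %.2f%%)",
                n_emitted, len(records), 100 * n_cropped / max(n_emitted, 1))
    inputs1 = np.stack(segs_all)
    inputs2 = spectral_matrix(inputs1)
    return Dataset.from_indices(inputs1, inputs2, np.array(labels), np.array(groups))


def write_archive(ds: Dataset, path: str | Path, config: PipelineConfig) -> Path:
    """Write a prepared dataset + manifest as a compressed npz archive."""
    import json

    path = Path(path)
    np.savez_compressed(
        path, inputs1=ds.inputs1, inputs2=ds.inputs2, labels=ds.labels,
        groups=np.asarray(ds.groups, dtype=str),
        manifest=json.dumps(config.to_dict()),
    )
    return path


def load_archive(path: str | Path) -> Dataset:
    z = np.load(path, allow_pickle=False)
    return Dataset(z["inputs1"], z["inputs2"], z["labels"], z["groups"])


def train_fold(train_ds: Dataset, val_ds: Dataset, test_ds: Dataset,
               cfg: PipelineConfig, seed: int = 0):
    """Train one CV fold and evaluate on the test set.

    Standardizers (one per input channel) and class weights are fitted on
    the training fold only.  Returns (test ConfusionMatrix, history).
    """
    from .evaluator import confusion_matrix

    s1 = fit_standardizer(train_ds.inputs1)
    s2 = fit_standardizer(train_ds.inputs2)

    def std(ds: Dataset) -> Dataset:
        return Dataset(s1.apply(ds.inputs1), s2.apply(ds.inputs2),
                       ds.labels, ds.groups)

    counts = np.bincount(train_ds.y, minlength=4)
    weights = class_weights(counts) if cfg.use_class_weights else None
    model = build_owcnn(cfg.model, seed=seed)
    tcfg = cfg.train_config(seed=seed, weights=weights)
    hist = train(model, std(train_ds), std(val_ds), tcfg)
    test_std = std(test_ds)
    pred = model.predict(test_std.inputs1, test_std.inputs2)
    cm = confusion_matrix(test_ds.y, pred)
    return cm, hist


def run_all(records, cfg: PipelineConfig | None = None):
    """Full pipeline: prepare -> protocol training -> report."""
    from .evaluator import run_protocol

    cfg = cfg or PipelineConfig()
    logger.info("pipeline config: %s", cfg.to_dict())
    return run_protocol(cfg.protocol, records, cfg, seed=cfg.seed,
                        n_folds=cfg.n_folds)
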