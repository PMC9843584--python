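"""End-to-end experiment orchestration: augment -> encode -> train -> evaluate.

A :class:`RunConfig` fully describes one experimental condition on a
synthetic dataset (or a user CSV): how the data are generated and split, the
training-set fraction or class-imbalance ratio, the augmentation condition,
the encoding scheme, the model and the training discipline. Every random
draw derives from seeds stored in the config, so re-running a config
reproduces all serialized numbers bit for bit.

Conditions:

``aa_baseline``
    Train on the amino-acid sequences (unigram encoding, vocabulary 21).
``dna_baseline``
    Train on one reverse translation per sequence, no augmentation.
``offline_nta``
    Expand the training set ``n_aug``-fold before training (iterative or
    random codon sampling); for classification only the minority class is
    expanded and the majority class is reverse translated once.
``online_nta``
    Constant dataset size; probabilistic codon substitution per mini-batch,
    fixed epoch count.

Validation and test sets are reverse translated without augmentation, using
deterministic codon sampling when the training condition samples iteratively
and random sampling otherwise; test metrics are averaged over five
reverse-translation replicates of the test set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codon_model, data_pipeline, models_training, synthetic_data
from .augmentation import AugmentationConfig, OnlineAugmentConfig, augment_dataset_offline
from .data_pipeline import SplitSpec
from .dataset import LabeledDataset
from .encoding import build_vocabulary, n_tokens
from .errors import ConfigError
from .evaluation import MetricResult, aggregate
from .models_training import ModelConfig, TrainConfig, build_model, predict, predict_class

__all__ = ["RunConfig", "run_experiment", "run_grid", "CONDITIONS"]

CONDITIONS = ("aa_baseline", "dna_baseline", "offline_nta", "online_nta")


@dataclass(frozen=True)
class RunConfig:
    """One experimental cell. See the module docstring for the semantics."""

    task: str = "regression"
    condition: str = "offline_nta"
    # data (synthetic presets; or csv_path to bring your own amino-acid CSV)
    csv_path: str | None = None
    data_seed: int = 0
    n_variants: int = 3000
    noise_sd: float = 0.1
    max_ed: int = 4
    ed_threshold: int = 3
    valid_fraction: float = 0.2
    train_fraction: float = 1.0
    positive_ratio: float | None = None
    # augmentation
    method: str = "random"  # iterative | random (offline codon sampling)
    n_aug: int = 10
    table: str = "natural"  # natural | balanced | shuffled
    table_seed: int = 0
    t_aug: float = 0.5
    num_subs: float = 0.25
    # encoding & model
    scheme: str = "nt_trigram"
    family: str = "cnn"
    preset: str = "desk"
    # training
    epochs: int = 30
    patience: int = 10
    batch_size: int = 32
    lr: float = 0.01
    class_weighted_sampling: bool = False
    clip_norm: float | None = None
    # evaluation
    n_replicates: int = 5
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"unknown task {self.task!r}")
        if not 0.0 < self.train_fraction <= 1.0:
            raise ConfigError(f"train_fraction must be in (0, 1], got {self.train_fraction}")
        if self.positive_ratio is not None and not 0.0 < self.positive_ratio <= 1.0:
            raise ConfigError(f"positive_ratio must be in (0, 1], got {self.positive_ratio}")
        if self.condition == "aa_baseline" and self.scheme != "aa_unigram":
            object.__setattr__(self, "scheme", "aa_unigram")
        if self.condition != "aa_baseline" and self.scheme == "aa_unigram":
            raise ConfigError("nucleotide conditions need a nucleotide encoding scheme")
        if self.condition == "online_nta" and self.method == "iterative":
            raise ConfigError("online augmentation uses random codon sampling")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "seeds" in data:
            data = {**data, "seeds": tuple(data["seeds"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        return d


def _codon_table(cfg: RunConfig) -> codon_model.CodonTable:
    if cfg.table == "natural":
        return codon_model.natural_table()
    if cfg.table == "balanced":
        return codon_model.balanced_table(cfg.table_seed)
    if cfg.table == "shuffled":
        return codon_model.shuffled_table(cfg.table_seed)
    raise ConfigError(f"unknown codon table {cfg.table!r}")


def _load_split_dataset(cfg: RunConfig) -> LabeledDataset:
    """Generate (or read) the amino-acid dataset and tag train/valid/test."""
    if cfg.csv_path is not None:
        data = data_pipeline.read_dataset(cfg.csv_path, alphabet="amino_acid", task=cfg.task)
        if all(r.split != "unassigned" for r in data):
            return data
        raise ConfigError("CSV datasets must carry a 'set' column with split tags")
    if cfg.task == "regression":
        spec = synthetic_data.gb1_like_spec(seed=cfg.data_seed, noise_sd=cfg.noise_sd)
        data = synthetic_data.generate_landscape(spec, cfg.n_variants, cfg.max_ed)
        wt = spec.wild_type
    else:
        spec = synthetic_data.cdrh3_like_spec(seed=cfg.data_seed, noise_sd=cfg.noise_sd)
        data = synthetic_data.generate_binder_dataset(spec, cfg.n_variants, cfg.max_ed)
        wt = spec.wild_type
    split = SplitSpec(
        wild_type=wt, ed_threshold=cfg.ed_threshold, valid_fraction=cfg.valid_fraction
    )
    return data_pipeline.split_by_edit_distance(data, split, seed=cfg.data_seed)


def _prepare_training_sets(
    cfg: RunConfig, data: LabeledDataset, seed: int
) -> tuple[LabeledDataset, LabeledDataset, list[LabeledDataset], str]:
    """Build the (possibly augmented) train set, valid set and test replicates
    for one model seed. Returns (train, valid, replicates, rt_mode)."""
    table = _codon_table(cfg)
    train = data.subset("train")
    valid = data.subset("valid")
    test = data.subset("test")

    if cfg.task == "regression" and cfg.train_fraction < 1.0:
        train = data_pipeline.stratified_truncate(
            train, cfg.train_fraction, seed=cfg.data_seed
        )
    if cfg.task == "classification" and cfg.positive_ratio is not None:
        train = data_pipeline.impose_class_imbalance(
            train, cfg.positive_ratio, seed=cfg.data_seed
        )

    # codon sampling mode mirrored by valid/test reverse translation
    rt_mode = (
        "deterministic"
        if cfg.condition in ("offline_nta", "dna_baseline") and cfg.method == "iterative"
        else "random"
    )

    if cfg.condition == "aa_baseline":
        return train, valid, [test], rt_mode

    if cfg.condition == "offline_nta":
        if cfg.task == "classification":
            train_nt = data_pipeline.augment_minority_class(
                train,
                AugmentationConfig(cfg.n_aug, cfg.method, table, seed=seed),
            )
        else:
            train_nt = augment_dataset_offline(
                train, AugmentationConfig(cfg.n_aug, cfg.method, table, seed=seed)
            )
    else:  # dna_baseline or online_nta: one reverse translation per sequence
        base_method = cfg.method if cfg.condition == "dna_baseline" else "random"
        train_nt = augment_dataset_offline(
            train, AugmentationConfig(1, base_method, table, seed=seed)
        )

    valid_nt = data_pipeline.make_test_replicates(
        valid, table, mode=rt_mode, base_seed=seed + 1000, k=1
    ).replicates[0]
    replicates = list(
        data_pipeline.make_test_replicates(
            test, table, mode=rt_mode, base_seed=seed + 2000, k=cfg.n_replicates
        ).replicates
    )
    return train_nt, valid_nt, replicates, rt_mode


def _run_one_seed(cfg: RunConfig, data: LabeledDataset, seed: int) -> dict:
    train_set, valid_set, replicates, _ = _prepare_training_sets(cfg, data, seed)
    vocab = build_vocabulary(cfg.scheme)
    seq_len = max(len(s) for s in train_set.sequences + valid_set.sequences)
    max_len = n_tokens(seq_len, cfg.scheme)
    model = build_model(
        ModelConfig(family=cfg.family, task=cfg.task, preset=cfg.preset, seed=seed),
        vocab,
        max_len,
    )
    tc = TrainConfig(
        mode="online" if cfg.condition == "online_nta" else "offline",
        epochs=cfg.epochs,
        patience=cfg.patience,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        seed=seed,
        online_cfg=(
            OnlineAugmentConfig(cfg.t_aug, cfg.num_subs, _codon_table(cfg), seed=seed)
            if cfg.condition == "online_nta"
            else None
        ),
        class_weighted_sampling=cfg.class_weighted_sampling,
        clip_norm=cfg.clip_norm,
    )
    result = models_training.train(model, train_set, valid_set, tc)
    replicate_scores = []
    for rep in replicates:
        if cfg.task == "regression":
            from .evaluation import spearman_rho

            score = spearman_rho(predict(model, rep.sequences), rep.labels)
        else:
            from .evaluation import mcc

            score = mcc(predict_class(model, rep.sequences), rep.labels.astype(int))
        replicate_scores.append(score)
    return {
        "seed": seed,
        "replicate_scores": replicate_scores,
        "history": result.history,
        "n_train": len(train_set),
        "n_valid": len(valid_set),
        "n_test": len(replicates[0]),
    }


def run_experiment(cfg: RunConfig, out_dir: str | Path | None = None) -> MetricResult:
    """Run one condition across ``cfg.seeds`` and aggregate the test metric.

    When ``out_dir`` is given, writes ``manifest.json`` (config snapshot),
    ``curves.json`` (per-seed training histories) and ``metrics.json``
    (the aggregated result).
    """
    data = _load_split_dataset(cfg)
    per_seed = [_run_one_seed(cfg, data, seed) for seed in cfg.seeds]
    metric_name = "spearman_rho" if cfg.task == "regression" else "mcc"
    result = aggregate([r["replicate_scores"] for r in per_seed], metric_name)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": cfg.to_dict(), "version": _version()}, fh, indent=2)
        with open(out / "curves.json", "w") as fh:
            json.dump({str(r["seed"]): r["history"] for r in per_seed}, fh, indent=2)
        with open(out / "metrics.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
    return result


def run_grid(
    base: RunConfig,
    sweep: dict[str, list],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run a cartesian sweep over config fields; one row per cell.

    ``sweep`` maps RunConfig field names to value lists, e.g.
    ``{"train_fraction": [0.1, 0.5], "condition": ["dna_baseline",
    "offline_nta"]}``. Per-cell failures are recorded in the ``error`` column
    and the grid continues.
    """
    if not sweep or any(not v for v in sweep.values()):
        raise ConfigError("sweep must map field names to non-empty value lists")
    keys = list(sweep)
    rows = []
    for values in product(*(sweep[k] for k in keys)):
        cell = dict(zip(keys, values))
        row = dict(cell)
        try:
            cfg = dataclasses.replace(base, **cell)
            res = run_experiment(cfg)
            row.update(mean=res.mean, sd=res.sd, n_seeds=res.n_seeds, error=None)
        except Exception as exc:  # noqa: BLE001 - grid resilience by contract
            row.update(mean=np.nan, sd=np.nan, n_seeds=0, error=str(exc))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame


def _version() -> str:
    from . import __version__

    return __version__
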