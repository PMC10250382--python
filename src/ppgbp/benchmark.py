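"""Standard synthetic benchmarks for the full estimation system.

These are the package's reference experiments: generate the default
synthetic oscillometric dataset, train the two-stage system at desk scale
(reduced epochs with early stopping), and evaluate on held-out subjects,
together with two non-learning baselines:

* mean predictor — always outputs the training-set mean BP;
* envelope-peak oracle — reads the applied pressure at the oscillometric
  envelope maximum (the centre of the segmented force window), takes it as
  MAP, and inverts MAP = DBP + PP/3 with the training-population mean pulse
  pressure.

Problem sizes (200 subjects -> 160 train+validation / 40 test at 5 cases
each; stage-1 capped at 20 epochs) are the package's desk-scale study
conditions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import evaluate
from .evaluate import EvalReport, make_folds, make_report
from .model import (
    BPSystem,
    PreparedDataset,
    TrainConfig,
    train_full_system,
)
from .preprocess import prepare_case
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "BenchmarkResult",
    "prepare_dataset",
    "split_dataset",
    "envelope_peak_baseline",
    "run_default_benchmark",
    "run_informative_channel_benchmark",
    "run_ablation_benchmark",
]

# Desk-scale schedule: both stages stop early on validation MSE.  The
# attention stage works on cached latents, so its longer schedule is cheap.
STAGE1_EPOCHS = 20
STAGE1_PATIENCE = 4
ATTENTION_EPOCHS = 150
ATTENTION_PATIENCE = 15


@dataclass
class BenchmarkResult:
    target: str
    report: EvalReport
    y_ref: np.ndarray
    y_hat: np.ndarray
    weights: np.ndarray  # (n_test, 9) attention weights
    mean_baseline: EvalReport
    envelope_baseline: EvalReport
    system: BPSystem


def prepare_dataset(config: SimConfig) -> PreparedDataset:
    """Simulate and preprocess the full dataset."""
    recordings, _ = simulate_dataset(config)
    return PreparedDataset([prepare_case(r) for r in recordings])


def split_dataset(
    dataset: PreparedDataset, seed: int, val_fraction: float = 0.2
) -> tuple[PreparedDataset, PreparedDataset, PreparedDataset]:
    """Subject-disjoint (train, validation, test) split.

    Fold 1 of a 5-fold subject split is the test set; `val_fraction` of the
    remaining subjects (again split by subject) form the early-stopping
    validation set.
    """
    split = make_folds(dataset.subject_ids, k=5, seed=seed)
    test_subjects = split.test_subjects(1)
    trainval = sorted(split.train_subjects(1))
    k_val = max(2, int(round(1.0 / val_fraction)))
    val_split = make_folds(trainval, k=k_val, seed=seed + 1)
    val_subjects = val_split.test_subjects(1)

    def subset(subjects: set[str]) -> PreparedDataset:
        idx = np.where(np.isin(dataset.subject_ids, list(subjects)))[0]
        return dataset.subset(idx)

    train_subjects = set(trainval) - val_subjects
    return subset(train_subjects), subset(val_subjects), subset(test_subjects)


def envelope_peak_baseline(
    test_set: PreparedDataset,
    train_set: PreparedDataset,
    target: str,
    config: SimConfig,
) -> np.ndarray:
    """Analytic oscillometric estimate without any learning.

    The segmented force window is centred on the envelope maximum, so its
    middle sample is the force where applied pressure crossed MAP.  With the
    training population's mean pulse pressure PP: DBP = MAP - PP/3 and
    SBP = DBP + PP.
    """
    centre = test_set.x3[:, 0, test_set.x3.shape[2] // 2].astype(float)
    map_est = config.pressure_gain * centre
    pp = float(np.mean(train_set.sbp - train_set.dbp))
    dbp_est = map_est - pp / 3.0
    return dbp_est if target == "DBP" else dbp_est + pp


def run_default_benchmark(
    seed: int = 7,
    target: str = "DBP",
    n_subjects: int = 200,
    stage1_epochs: int = STAGE1_EPOCHS,
    sim_config: SimConfig | None = None,
    dataset: PreparedDataset | None = None,
) -> BenchmarkResult:
    """The standard held-out evaluation of the full two-stage system."""
    config = sim_config or SimConfig(n_subjects=n_subjects, seed=seed)
    if dataset is None:
        dataset = prepare_dataset(config)
    train_set, val_set, test_set = split_dataset(dataset, seed=seed)

    cfg = TrainConfig(
        target=target,
        epochs=stage1_epochs,
        patience=STAGE1_PATIENCE,
        seed=seed,
    )
    system = train_full_system(train_set, cfg, val_set, attention_cfg=_stage2(cfg))
    y_hat, weights = system.predict_batch(test_set)
    y_ref = test_set.labels(target)
    report = make_report(target, y_ref, y_hat)

    mean_hat = np.full_like(y_ref, train_set.labels(target).mean())
    mean_baseline = make_report(target, y_ref, mean_hat)
    env_hat = envelope_peak_baseline(test_set, train_set, target, config)
    env_baseline = make_report(target, y_ref, env_hat)

    return BenchmarkResult(
        target=target,
        report=report,
        y_ref=y_ref,
        y_hat=y_hat,
        weights=weights,
        mean_baseline=mean_baseline,
        envelope_baseline=env_baseline,
        system=system,
    )


def _stage2(cfg: TrainConfig) -> TrainConfig:
    return replace(
        cfg, stage="attention", epochs=ATTENTION_EPOCHS, patience=ATTENTION_PATIENCE
    )


def run_informative_channel_benchmark(
    seed: int = 7,
    target: str = "DBP",
    n_subjects: int = 200,
    stage1_epochs: int = STAGE1_EPOCHS,
) -> tuple[np.ndarray, int]:
    """Attention sanity benchmark: the finger sits exactly on the sensor
    centre with a tightly focused gain profile, so only the centre channel
    (5) carries the oscillometric signal and the rest are noise.

    Returns (mean attention weights over held-out cases, informative
    channel index, 1-based).
    """
    config = SimConfig(
        n_subjects=n_subjects,
        seed=seed,
        gain_spread=0.2,
        offset_sd=0.0,
    )
    dataset = prepare_dataset(config)
    train_set, val_set, test_set = split_dataset(dataset, seed=seed)
    cfg = TrainConfig(
        target=target, epochs=stage1_epochs, patience=STAGE1_PATIENCE, seed=seed
    )
    system = train_full_system(train_set, cfg, val_set, attention_cfg=_stage2(cfg))
    _, weights = system.predict_batch(test_set)
    informative = 5  # grid centre, row-major 3x3
    return weights.mean(axis=0), informative


def run_ablation_benchmark(
    seed: int = 7,
    target: str = "DBP",
    channel: int = 5,
    n_subjects: int = 200,
    stage1_epochs: int = STAGE1_EPOCHS,
    dataset: PreparedDataset | None = None,
) -> dict[str, float]:
    """Input-combination ablation on one single-channel extractor of the
    default benchmark.

    Trains the same extractor with all streams (P+E+F), without envelopes
    (P+F) and without raw PPG (E+F), and reports the best validation MSE
    per mode (mmHg^2).
    """
    import copy as _copy

    from .model import train_single_channel

    config = SimConfig(n_subjects=n_subjects, seed=seed)
    if dataset is None:
        dataset = prepare_dataset(config)
    train_set, val_set, _ = split_dataset(dataset, seed=seed)

    def masked(ds: PreparedDataset, mode: str) -> PreparedDataset:
        if mode == "P+E+F":
            return ds
        m = _copy.copy(ds)
        if mode == "P+F":
            m.x2 = np.zeros_like(ds.x2)
        else:
            m.x1 = np.zeros_like(ds.x1)
        return m

    out: dict[str, float] = {}
    for mode in ("P+E+F", "P+F", "E+F"):
        cfg = TrainConfig(
            target=target, epochs=stage1_epochs, patience=STAGE1_PATIENCE, seed=seed
        )
        trained = train_single_channel(
            masked(train_set, mode), channel, cfg, masked(val_set, mode)
        )
        out[mode] = float(trained.val_mse)
    return out
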