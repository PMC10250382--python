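"""End-to-end pipeline: simulate -> preprocess -> two-stage training ->
subject-disjoint cross-validated evaluation, with all artifacts written
under one run directory keyed by the config hash."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .benchmark import split_dataset
from .config import PipelineConfig, save_config
from .evaluate import (
    attention_group_report,
    bland_altman_plot,
    make_report,
    scatter_plot,
)
from .model import N_CHANNELS, BPSystem, PreparedDataset, train_full_system
from .preprocess import prepare_case

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "save_system", "load_system"]


def save_system(system: BPSystem, path: Path, meta: dict | None = None) -> None:
    """Checkpoint: all extractor states + attention head + metadata."""
    arrays: dict[str, np.ndarray] = {}
    for ch, ext in enumerate(system.extractors, start=1):
        for key, val in ext.extractor.state_dict().items():
            arrays[f"e{ch}_{key}"] = val
        arrays[f"e{ch}_ystats"] = np.array([ext.y_mean, ext.y_std])
    arrays["att_omega"] = system.attention.omega
    arrays["att_b"] = np.array([system.attention.b])
    arrays["att_v"] = system.attention.v
    arrays["att_c"] = np.array([system.attention.c])
    info = {
        "target": system.target,
        "y_mean": system.y_mean,
        "y_std": system.y_std,
        "channel_ranking": system.channel_ranking,
        **(meta or {}),
    }
    np.savez_compressed(path, meta=json.dumps(info), **arrays)


def load_system(path: Path) -> BPSystem:
    from .model import AttentionHead, TrainedExtractor, build_extractor

    with np.load(path) as z:
        info = json.loads(str(z["meta"]))
        extractors = []
        for ch in range(1, N_CHANNELS + 1):
            ext = build_extractor(seed=0)
            prefix = f"e{ch}_"
            state = {
                k[len(prefix):]: z[k]
                for k in z.files
                if k.startswith(prefix) and k != f"{prefix}ystats"
            }
            ext.load_state_dict(state)
            ym, ys = z[f"{prefix}ystats"]
            extractors.append(
                TrainedExtractor(
                    extractor=ext,
                    channel_index=ch,
                    target=info["target"],
                    y_mean=float(ym),
                    y_std=float(ys),
                )
            )
        head = AttentionHead(
            omega=z["att_omega"].astype(float),
            b=float(z["att_b"][0]),
            v=z["att_v"].astype(float),
            c=float(z["att_c"][0]),
        )
    return BPSystem(
        target=info["target"],
        extractors=extractors,
        attention=head,
        y_mean=info["y_mean"],
        y_std=info["y_std"],
        channel_ranking=info.get("channel_ranking"),
    )


def run_pipeline(
    config: PipelineConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    skip_simulate: bool = False,
    dataset_dir: str | Path | None = None,
) -> Path:
    """Execute the full pipeline and return the run directory."""
    seed = config.seed if seed is None else seed
    root = Path(out_dir or config.out_dir) / f"run-{config.config_hash()}-s{seed}"
    root.mkdir(parents=True, exist_ok=True)
    save_config(config, root / "config.yaml")

    data_dir = Path(dataset_dir) if dataset_dir else root / "dataset"
    if skip_simulate:
        if not (data_dir / "manifest.csv").exists():
            raise FileNotFoundError(f"--skip-simulate: no dataset at {data_dir}")
        logger.info("stage simulate: skipped, reading %s", data_dir)
        recordings = pio.read_dataset(data_dir)
    else:
        from .simulate import simulate_dataset

        logger.info("stage simulate: %d subjects", config.simulate.n_subjects)
        recordings, table = simulate_dataset(config.simulate.to_sim_config(seed))
        pio.write_dataset(recordings, data_dir, table)

    logger.info("stage preprocess: %d cases", len(recordings))
    cases = [prepare_case(r) for r in recordings]
    pio.write_prepared(cases, root / "prepared")
    dataset = PreparedDataset(cases)
    train_set, val_set, test_set = split_dataset(
        dataset, seed=seed, val_fraction=config.evaluate.val_fraction
    )

    results: dict[str, dict] = {}
    for target in config.targets:
        logger.info("stage train: target %s", target)
        cfg = config.train.to_train_config(target, seed)
        system = train_full_system(
            train_set, cfg, val_set, config.train.to_extractor_config()
        )
        save_system(
            system,
            root / f"system_{target.lower()}.npz",
            meta={"seed": seed, "config_hash": config.config_hash()},
        )
        y_hat, weights = system.predict_batch(test_set)
        y_ref = test_set.labels(target)
        if not np.isfinite(y_hat).all():
            raise RuntimeError(f"stage evaluate: non-finite predictions for {target}")
        report = make_report(target, y_ref, y_hat)
        groups = attention_group_report(test_set.sbp, test_set.dbp, weights)
        results[target] = {
            "report": report.to_dict(),
            "attention_groups": {
                g: {
                    "n": v["n"],
                    "mean_weights": None
                    if v["mean_weights"] is None
                    else [float(x) for x in v["mean_weights"]],
                }
                for g, v in groups.items()
            },
        }
        scatter_plot(y_ref, y_hat, target, root / f"scatter_{target.lower()}.png")
        bland_altman_plot(
            y_ref, y_hat, target, root / f"bland_altman_{target.lower()}.png"
        )
        pd.DataFrame([report.to_dict()]).to_csv(
            root / f"report_{target.lower()}.csv", index=False
        )

    (root / "reports.json").write_text(json.dumps(results, indent=1))
    logger.info("pipeline complete: %s", root)
    return root
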