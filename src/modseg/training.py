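"""Seeded SGD training, held-out evaluation, and the variant-sweep harness.

Training follows the stated recipe for this family of networks: stochastic
gradient descent with momentum 0.9 and weight decay 5e-4, batch size 1,
Kaiming-initialised parameters, cross-entropy + Dice loss, and patches of
``patch_depth`` axial slices sampled uniformly at random from the training
cases. The default learning rate is 1e-3; small desk-scale experiments in
this package use 1e-2 (both are plain config values).

``run_experiment`` sweeps the five network variants under matched seeds and
budgets and writes one results row per variant with the nine
{Dice, Sensitivity, PPV} × {WT, TC, ET} columns, together with full
provenance (configuration, seeds, run id).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .autodiff import SGD
from .metrics import (LossConfig, METRIC_NAMES, REGIONS, combined_loss,
                      evaluate_masks, mean_foreground_dice)
from .network import (NetworkConfig, SegmentationModel, build_model,
                      predict_case)
from .phantoms import PhantomSpec, generate_case
from .preprocess import PreprocessConfig, preprocess_case
from .volumes import Case


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 1
    max_iterations: int = 400
    patch: tuple[int, int, int] = (144, 144, 16)    # (H, W, D)
    seed: int = 0
    checkpoint_every: int = 0                        # 0 = only final

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_iterations < 0:
            raise ValueError("lr must be > 0, batch_size >= 1, "
                             "max_iterations >= 0")


@dataclass
class RunRecord:
    losses: list[float]
    config: TrainConfig
    checkpoint_path: Optional[Path] = None
    seed: int = 0

    def __post_init__(self):
        if any(not np.isfinite(v) for v in self.losses):
            raise ValueError("loss trace contains non-finite values")


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, opt: SGD, iteration: int,
                    rng: np.random.Generator, losses: Sequence[float],
                    path: Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"m{i}": b for i, b in enumerate(opt._buffers)})
    arrays["iteration"] = np.array(iteration)
    arrays["losses"] = np.asarray(losses, dtype=np.float64)
    arrays["rng_state"] = np.frombuffer(
        json.dumps(rng.bit_generator.state).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(model: SegmentationModel, opt: Optional[SGD], path: Path
                    ) -> tuple[int, list[float], dict]:
    with np.load(path) as data:
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
        if opt is not None:
            for i, b in enumerate(opt._buffers):
                b[...] = data[f"m{i}"]
        iteration = int(data["iteration"])
        losses = data["losses"].tolist()
        state = json.loads(bytes(data["rng_state"]).decode())
    return iteration, losses, state


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sample_patch(images: np.ndarray, labels: np.ndarray, patch_depth: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    depth = images.shape[1]
    if depth <= patch_depth:
        pad = patch_depth - depth
        if pad:
            images = np.pad(images, ((0, 0), (0, pad), (0, 0), (0, 0)))
            labels = np.pad(labels, ((0, pad), (0, 0), (0, 0)))
        return images, labels
    start = int(rng.integers(0, depth - patch_depth + 1))
    return (images[:, start:start + patch_depth],
            labels[start:start + patch_depth])


def train(net_config: NetworkConfig, train_cases: Sequence[Case],
          train_config: TrainConfig,
          pre_config: Optional[PreprocessConfig] = None,
          loss_config: LossConfig = LossConfig(),
          checkpoint_dir: Optional[Path] = None,
          resume_from: Optional[Path] = None,
          verbose: bool = False) -> tuple[SegmentationModel, RunRecord]:
    """Run seeded SGD on combined CE + Dice loss over random depth patches.

    Deterministic under a fixed seed (single-threaded numpy). Checkpoints
    carry parameters, momentum buffers and the sampler RNG state, so a
    resumed run reproduces the uninterrupted loss trace exactly.
    """
    if not train_cases:
        raise ValueError("at least one training case required")
    h, w, d = train_config.patch
    if pre_config is None:
        pre_config = PreprocessConfig(target_axial=(h, w), patch_depth=d)
    model = build_model(net_config)
    opt = SGD(model.parameters(), lr=train_config.lr,
              momentum=train_config.momentum,
              weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    start_iter, losses = 0, []
    if resume_from is not None:
        start_iter, losses, state = load_checkpoint(model, opt, resume_from)
        rng.bit_generator.state = state

    prepped = []
    for case in train_cases:
        images, labels, _ = preprocess_case(case, pre_config)
        if labels is None:
            raise ValueError(f"training case {case.id} has no ground truth")
        prepped.append((images, labels))

    for it in range(start_iter, train_config.max_iterations):
        batch_loss = 0.0
        opt.zero_grad()
        for _ in range(train_config.batch_size):
            images, labels = prepped[int(rng.integers(len(prepped)))]
            imgs, labs = _sample_patch(images, labels,
                                       pre_config.patch_depth, rng)
            probs, _ = model.forward(imgs[None])
            loss = combined_loss(probs, labs, loss_config)
            loss.backward(np.full((), 1.0 / train_config.batch_size))
            batch_loss += float(loss.data) / train_config.batch_size
        if not np.isfinite(batch_loss):
            raise RuntimeError(
                f"loss became non-finite at iteration {it}; the learning "
                "rate is likely too high or the data degenerate")
        opt.step()
        losses.append(batch_loss)
        if verbose and (it % 20 == 0 or it == train_config.max_iterations - 1):
            print(f"iter {it:4d}  loss {batch_loss:.4f}")
        if (checkpoint_dir and train_config.checkpoint_every
                and (it + 1) % train_config.checkpoint_every == 0):
            save_checkpoint(model, opt, it + 1, rng, losses,
                            Path(checkpoint_dir) / f"iter{it + 1:05d}.npz")

    record = RunRecord(losses=losses, config=train_config,
                       seed=train_config.seed)
    if checkpoint_dir:
        final = Path(checkpoint_dir) / "final.npz"
        save_checkpoint(model, opt, train_config.max_iterations, rng,
                        losses, final)
        record.checkpoint_path = final
    return model, record


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model: SegmentationModel, test_cases: Sequence[Case],
             pre_config: PreprocessConfig) -> pd.DataFrame:
    """Per-case region metrics plus a ``mean`` row (per-case average).

    Long format: columns case_id, region, dice, sensitivity, ppv. Cases are
    predicted via depth windows + reassembly and scored on their original
    grids.
    """
    if not test_cases:
        raise ValueError("empty test case list")
    rows = []
    for case in test_cases:
        if case.truth is None:
            raise ValueError(f"test case {case.id} has no ground truth")
        pred = predict_case(model, case, pre_config)
        table = evaluate_masks(pred.labels, case.truth.labels)
        for region, r in table.iterrows():
            rows.append({"case_id": case.id, "region": region, **r.to_dict()})
    df = pd.DataFrame(rows)
    means = df.groupby("region", sort=False)[list(METRIC_NAMES)].mean()
    for region, r in means.iterrows():
        rows.append({"case_id": "mean", "region": region, **r.to_dict()})
    return pd.DataFrame(rows, columns=["case_id", "region", *METRIC_NAMES])


def mean_metrics_row(df: pd.DataFrame) -> dict[str, float]:
    """Flatten the ``mean`` rows of an evaluate() table into the nine
    {metric}_{region} columns."""
    out = {}
    mean = df[df.case_id == "mean"].set_index("region")
    for metric in METRIC_NAMES:
        for region in REGIONS:
            out[f"{metric}_{region}"] = float(mean.loc[region, metric])
    return out


def evaluate_mean_foreground_dice(model: SegmentationModel,
                                  test_cases: Sequence[Case],
                                  pre_config: PreprocessConfig) -> float:
    scores = [mean_foreground_dice(
        predict_case(model, c, pre_config).labels, c.truth.labels)
        for c in test_cases]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Variant sweep (the ablation harness)
# ---------------------------------------------------------------------------

def run_experiment(config: dict | str | Path,
                   out_dir: Optional[Path] = None,
                   verbose: bool = False) -> pd.DataFrame:
    """Train and evaluate a set of network variants under matched phantom
    data, seeds and budgets; returns (and optionally writes) the results
    table with one row per variant and nine metric columns.

    The experiment YAML/dict holds blocks ``phantom``, ``network``, ``train``,
    ``preprocess`` (each mirroring the corresponding dataclass), plus
    ``variants`` (list), ``n_train``, ``n_test`` and ``seed``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    ph_kwargs = dict(config.get("phantom", {}))
    for key in ("dims", "lesion_count_range", "lesion_radius_range"):
        if key in ph_kwargs:
            ph_kwargs[key] = tuple(ph_kwargs[key])
    if "contrast" in ph_kwargs and ph_kwargs["contrast"] is not None:
        ph_kwargs["contrast"] = np.asarray(ph_kwargs["contrast"], dtype=float)
    phantom = PhantomSpec(**{**ph_kwargs, "seed": seed})
    n_train = int(config.get("n_train", 10))
    n_test = int(config.get("n_test", 5))
    variants = config.get("variants", ["multi_shared",
                                       "multi_shared_attention"])
    net_kwargs = dict(config.get("network", {}))
    train_kwargs = dict(config.get("train", {}))
    pre_kwargs = dict(config.get("preprocess", {}))
    for kw in (net_kwargs, train_kwargs):
        for key in ("patch", "target_axial"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
    if "target_axial" in pre_kwargs:
        pre_kwargs["target_axial"] = tuple(pre_kwargs["target_axial"])

    train_cases = [generate_case(phantom, i) for i in range(n_train)]
    test_cases = [generate_case(phantom, n_train + i) for i in range(n_test)]

    pre = PreprocessConfig(**pre_kwargs) if pre_kwargs else PreprocessConfig(
        target_axial=phantom.dims[1:], patch_depth=min(16, phantom.dims[0]))
    rows = []
    per_variant_tables = {}
    for variant in variants:
        ncfg = NetworkConfig(variant=variant,
                             n_modalities=phantom.n_modalities,
                             n_classes=phantom.n_classes,
                             seed=seed, **net_kwargs)
        tcfg = TrainConfig(seed=seed, **train_kwargs)
        t0 = time.time()
        model, record = train(ncfg, train_cases, tcfg, pre_config=pre,
                              verbose=verbose)
        table = evaluate(model, test_cases, pre)
        per_variant_tables[variant] = table
        row = {"variant": variant, **mean_metrics_row(table),
               "final_loss": record.losses[-1] if record.losses else np.nan,
               "train_seconds": round(time.time() - t0, 1)}
        rows.append(row)
        if verbose:
            print(f"{variant}: dice_WT={row['dice_WT']:.3f} "
                  f"({row['train_seconds']}s)")
    results = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False)
        for variant, table in per_variant_tables.items():
            table.to_csv(out_dir / f"cases_{variant}.csv", index=False)
        provenance = {
            "config": _jsonable(config),
            "seed": seed,
            "run_id": hashlib.sha256(
                json.dumps(_jsonable(config), sort_keys=True).encode()
            ).hexdigest()[:12],
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
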