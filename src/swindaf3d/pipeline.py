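"""Training loop, cross-validation harness, checkpointing and sensitivity sweep.

The training protocol mirrors the clinical study at configurable scale: Adam
(lr 1e-4, weight decay 1e-4), batch size one, 50 epochs, model selection by
the highest validation Dice of the binarised main prediction.  Everything is
seeded: fold assignment, parameter initialisation, data order and
augmentation draws, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff.optim import Adam
from .losses import LossWeights, output_loss, total_loss
from .metrics import evaluate_masks
from .model import ModelConfig, SwinDAF3D
from .phantom import AugmentationConfig, augment
from .stats import FoldTable, summarize_folds
from .unet3d import UNet3D


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 1           # gradient accumulation count per update
    seed: int = 0
    selection_metric: str = "dsc"
    threshold: float = 0.5
    max_steps: int | None = None  # cap on optimiser updates (desk-scale runs)
    eval_every: int = 1           # epochs between validation passes
    stop_at_val_dsc: float | None = None  # early stop once validation DSC reaches this
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augmentation: AugmentationConfig | None = None
    verbose: bool = False

    def __post_init__(self):
        if min(self.lr, self.weight_decay) < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass
class CVPlan:
    k: int
    assignments: dict          # case id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [cid for cid, f in self.assignments.items() if f == fold]


@dataclass
class RunRecord:
    epochs: list               # one dict per logged epoch
    best_epoch: int
    best_val_dsc: float
    checkpoint_path: str | None
    steps: int


def make_folds(case_ids, k: int, seed: int = 0, groups: dict | None = None) -> CVPlan:
    """Seeded shuffle + round-robin fold assignment.

    With ``groups`` (case id -> group label, e.g. patient id) whole groups are
    assigned round-robin so no group straddles folds.
    """
    case_ids = list(case_ids)
    if k < 1 or k > len(case_ids):
        raise ValueError(f"k={k} incompatible with {len(case_ids)} cases")
    rng = np.random.default_rng(seed)
    assignments = {}
    if groups is None:
        order = [case_ids[i] for i in rng.permutation(len(case_ids))]
        for i, cid in enumerate(order):
            assignments[cid] = i % k
    else:
        labels = list(dict.fromkeys(groups[cid] for cid in case_ids))
        order = [labels[i] for i in rng.permutation(len(labels))]
        fold_of = {lab: i % k for i, lab in enumerate(order)}
        for cid in case_ids:
            assignments[cid] = fold_of[groups[cid]]
    return CVPlan(k=k, assignments=assignments, seed=seed)


def _model_loss(model, pred, truth, weights, is_daf: bool):
    if is_daf:
        bd = total_loss(pred, truth, weights)
        return bd.total_tensor, bd.total
    loss_t = output_loss(pred, truth)
    return loss_t, float(loss_t.data)


def _predict_mask(model, case, threshold):
    return model.predict_mask(case.volume.data, threshold)


def _mean_val_dsc(model, cases, threshold):
    from .metrics import dice_score
    return float(np.mean([dice_score(_predict_mask(model, c, threshold), c.mask.data)
                          for c in cases]))


def train(model, train_cases, val_cases, config: TrainConfig,
          checkpoint_path=None) -> RunRecord:
    """Train ``model`` (SwinDAF3D or UNet3D) and checkpoint the best-val-DSC state."""
    if not train_cases or not val_cases:
        raise ValueError("train and validation splits must be non-empty")
    is_daf = isinstance(model, SwinDAF3D)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    records = []
    best = {"epoch": -1, "dsc": -1.0, "state": None}
    steps = 0
    stop = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_cases))
        epoch_losses = []
        pending = 0
        model.zero_grad()
        for idx in order:
            case = train_cases[idx]
            if config.augmentation is not None:
                case = augment(case, config.augmentation,
                               rng=np.random.default_rng(rng.integers(2 ** 31)))
            pred = model(case.volume.data)
            truth = case.mask.data.astype(np.float32)
            if is_daf:
                loss_t, loss_v = _model_loss(model, pred, truth, config.loss_weights, True)
            else:
                loss_t, loss_v = _model_loss(model, pred, truth, None, False)
            if not np.isfinite(loss_v):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {steps}: {loss_v}")
            loss_t.backward()
            epoch_losses.append(loss_v)
            pending += 1
            if pending >= config.batch_size:
                if config.batch_size > 1:
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad /= config.batch_size
                opt.step()
                model.zero_grad()
                pending = 0
                steps += 1
                if config.max_steps is not None and steps >= config.max_steps:
                    stop = True
                    break
        if pending:
            opt.step()
            model.zero_grad()
            steps += 1

        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "steps": steps}
        if epoch % config.eval_every == 0 or stop or epoch == config.epochs - 1:
            val_dsc = _mean_val_dsc(model, val_cases, config.threshold)
            rec["val_dsc"] = val_dsc
            if val_dsc > best["dsc"]:
                best = {"epoch": epoch, "dsc": val_dsc, "state": model.state_dict()}
            if config.stop_at_val_dsc is not None and val_dsc >= config.stop_at_val_dsc:
                stop = True
        records.append(rec)
        if config.verbose:
            print(f"epoch {epoch}: loss {rec['train_loss']:.4f}"
                  + (f" val_dsc {rec.get('val_dsc', float('nan')):.4f}" if "val_dsc" in rec else ""))
        if stop:
            break

    if best["state"] is not None:
        model.load_state_dict(best["state"])
    path_str = None
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model)
        path_str = str(checkpoint_path)
    return RunRecord(epochs=records, best_epoch=best["epoch"],
                     best_val_dsc=best["dsc"], checkpoint_path=path_str, steps=steps)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _config_dict(model) -> dict:
    if isinstance(model, SwinDAF3D):
        return {"kind": "swindaf3d", "encoder": asdict(model.config.encoder),
                "head": asdict(model.config.head), "seed": model.config.seed}
    return {"kind": "unet3d", "base_width": model.enc[0].conv1.weight.data.shape[-1]}


def save_checkpoint(path, model) -> None:
    """Single-file npz archive: parameters plus a JSON config manifest."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(_config_dict(model)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    if cfg["kind"] == "swindaf3d":
        from .encoder import EncoderConfig
        from .head import HeadConfig
        enc = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in cfg["encoder"].items()})
        head_kwargs = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in cfg["head"].items()}
        model = SwinDAF3D(ModelConfig(encoder=enc, head=HeadConfig(**head_kwargs),
                                      seed=cfg["seed"]))
    elif cfg["kind"] == "unet3d":
        model = UNet3D(base_width=cfg["base_width"])
    else:
        raise ValueError(f"unknown checkpoint kind {cfg['kind']!r}")
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# evaluation / cross-validation / sweep
# ---------------------------------------------------------------------------

def evaluate(model_or_path, cases, threshold: float = 0.5,
             tolerance: float = 1.0) -> pd.DataFrame:
    """Per-case DSC / IoU / SDSC of binarised predictions, plus a mean row."""
    model = load_checkpoint(model_or_path) if isinstance(model_or_path, (str, Path)) \
        else model_or_path
    rows = []
    for case in cases:
        pred = model.predict_mask(case.volume.data, threshold)
        m = evaluate_masks(pred, case.mask.data, tolerance)
        rows.append((case.id, m.dsc, m.iou, m.sdsc))
    df = pd.DataFrame(rows, columns=["case", "dsc", "iou", "sdsc"])
    mean_row = pd.DataFrame([("mean", df["dsc"].mean(), df["iou"].mean(), df["sdsc"].mean())],
                            columns=df.columns)
    return pd.concat([df, mean_row], ignore_index=True)


def _build_model(model_config, seed=None):
    if isinstance(model_config, ModelConfig):
        if seed is not None:
            model_config = ModelConfig(encoder=model_config.encoder,
                                       head=model_config.head, seed=seed)
        return SwinDAF3D(model_config)
    raise TypeError(f"unsupported model config {type(model_config)}")


def run_cross_validation(cases, model_config: ModelConfig, train_config: TrainConfig,
                         k: int = 6, out_dir=None, groups: dict | None = None):
    """k-fold cross-validation; per-fold best-checkpoint metrics and summaries.

    Per fold, the checkpoint with the highest validation DSC is selected and
    all metrics are reported at that checkpoint.
    """
    if len(cases) < k:
        raise ValueError(f"need at least k={k} cases, got {len(cases)}")
    by_id = {c.id: c for c in cases}
    plan = make_folds(list(by_id), k, seed=train_config.seed, groups=groups)
    rows = []
    records = {}
    for fold in range(k):
        val_ids = set(plan.fold_ids(fold))
        train_cases = [c for c in cases if c.id not in val_ids]
        val_cases = [c for c in cases if c.id in val_ids]
        model = _build_model(model_config, seed=train_config.seed + fold)
        ckpt = (Path(out_dir) / f"fold{fold}.npz") if out_dir is not None else None
        rec = train(model, train_cases, val_cases, train_config, checkpoint_path=ckpt)
        records[fold] = rec
        df = evaluate(model, val_cases, train_config.threshold)
        mean = df[df["case"] == "mean"].iloc[0]
        for metric in ("dsc", "iou", "sdsc"):
            rows.append(("swindaf3d", metric, fold + 1, float(mean[metric])))
    table = FoldTable(pd.DataFrame(rows, columns=["model", "metric", "fold", "value"]))
    summaries = {metric: summarize_folds(table.values("swindaf3d", metric))
                 for metric in ("dsc", "iou", "sdsc")}
    return table, summaries, records


def sensitivity_sweep(feature_sizes=(24, 36, 48, 60), window_sizes=(3, 5, 7, 9),
                      base_feature: int = 48, base_window: int = 7,
                      lateral_channels: int = 64, volume_shape=(64, 64, 32),
                      mode: str = "shape", train_kwargs: dict | None = None) -> pd.DataFrame:
    """Feature-size and window-size sweep.

    ``mode='shape'`` instantiates each variant, counts parameters and
    forwards one random volume (recording success); ``mode='train'`` runs the
    full training protocol per variant (caller supplies data via
    ``train_kwargs``).  Infeasible variants are reported, not fatal.
    """
    from .encoder import EncoderConfig
    from .head import HeadConfig
    if not feature_sizes or not window_sizes:
        raise ValueError("sweep grids must be non-empty")
    variants = [(c, base_window) for c in feature_sizes]
    variants += [(base_feature, w) for w in window_sizes if (base_feature, w) not in variants]
    rows = []
    rng = np.random.default_rng(0)
    vol = rng.random(volume_shape, dtype=np.float32)
    for c, w in variants:
        row = {"feature_size": c, "window": w, "params": None, "forward_ok": False,
               "error": ""}
        try:
            heads = (3, 6, 12, 24) if c % 3 == 0 else (2, 4, 4, 8)
            cfg = ModelConfig(encoder=EncoderConfig(embed_dim=c, window=w, heads=heads,
                                                    depths=(1, 1, 1, 1)),
                              head=HeadConfig(lateral_channels=lateral_channels))
            model = SwinDAF3D(cfg)
            row["params"] = model.n_parameters()
            if mode == "shape":
                pred = model(vol)
                row["forward_ok"] = pred.main.shape == vol.shape
            elif mode == "train":
                kw = dict(train_kwargs or {})
                rec = train(model, kw["train_cases"], kw["val_cases"], kw["config"])
                row["forward_ok"] = True
                row["best_val_dsc"] = rec.best_val_dsc
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except (ValueError, FloatingPointError) as exc:  # infeasible variant
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
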