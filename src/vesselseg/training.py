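"""Training loop with plateau-driven learning-rate decay and early
stopping, the hyperparameter grid, ablation reporting, and hard-example
ranking.

The monitored loss (validation by default) drives a reduce-on-plateau
schedule: no improvement beyond ``min_delta`` for ``patience`` epochs is
a plateau event, each event multiplies the learning rate by ``factor``
and resets the patience window, and training stops at the fourth
consecutive plateau (improvement resets the consecutive count) or at
``max_epochs``.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ArchitectureConfig, build_model, count_parameters
from .losses import (
    DEFAULT_CLASSES,
    DEFAULT_SIGMA,
    compute_metrics,
    confusion_counts,
    harmonic_mean_loss,
    roc_auc,
    soft_loss,
)
from .nn import Adam


# --------------------------------------------------------------------------
# configuration and schedule
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 16
    learning_rate: float = 1e-4
    patience: int = 10
    lr_factor: float = 0.1
    max_plateaus: int = 4
    max_epochs: int = 300
    min_delta: float = 1e-4
    monitor: str = "val"  # "val" or "train"
    sigma: float = DEFAULT_SIGMA
    init_seed: int = 0
    shuffle_seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.monitor not in ("val", "train"):
            raise ValueError("monitor must be 'val' or 'train'")


class PlateauSchedule:
    """Reduce-on-plateau state machine, independent of any network."""

    def __init__(self, lr, patience=10, factor=0.1, max_plateaus=4, min_delta=1e-4):
        self.lr = float(lr)
        self.patience = patience
        self.factor = factor
        self.max_plateaus = max_plateaus
        self.min_delta = min_delta
        self.best = None  # first epoch sets the baseline, not an improvement
        self.since_improve = 0
        self.consecutive = 0

    def step(self, loss):
        """Feed one epoch's monitored loss; returns (plateau, stop)."""
        if self.best is not None and loss < self.best - self.min_delta:
            self.best = loss
            self.since_improve = 0
            self.consecutive = 0
            return False, False
        if self.best is None:
            self.best = loss
        self.since_improve += 1
        if self.since_improve >= self.patience:
            self.lr *= self.factor
            self.consecutive += 1
            self.since_improve = 0
            return True, self.consecutive >= self.max_plateaus
        return False, False


def simulate_schedule(losses, lr=1e-4, patience=10, factor=0.1, max_plateaus=4,
                      min_delta=1e-4):
    """Run the schedule over a scripted loss trace; returns an event table."""
    sched = PlateauSchedule(lr, patience, factor, max_plateaus, min_delta)
    rows = []
    for epoch, loss in enumerate(losses, start=1):
        plateau, stop = sched.step(float(loss))
        rows.append(
            {"epoch": epoch, "loss": float(loss), "lr": sched.lr,
             "plateau": plateau, "stop": stop}
        )
        if stop:
            break
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dataset plumbing
# --------------------------------------------------------------------------
def _as_pair(item):
    """Accept (image, mask) tuples or benchmark patches."""
    if isinstance(item, tuple):
        return item
    return item.image, item.scribble


def _to_batches(pairs, order, batch_size):
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        imgs = np.stack([np.asarray(pairs[i][0], np.float32) for i in idx])
        masks = np.stack([np.asarray(pairs[i][1]) for i in idx])
        yield imgs.transpose(0, 3, 1, 2), masks


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------
@dataclass
class TrainingResult:
    """Fit outcome: history, best checkpoint, and stop diagnostics."""

    model: object
    config: TrainingConfig
    history: pd.DataFrame
    best_epoch: int
    best_loss: float
    best_state: dict = field(repr=False, default=None)
    stop_reason: str = ""

    @property
    def epochs_trained(self):
        return len(self.history)

    def restore_best(self):
        if self.best_state is not None:
            self.model.load_state_dict(self.best_state)
        return self.model

    def summary(self):
        h = self.history
        lines = [
            "Training summary",
            "----------------",
            f"variant:          {self.model.config.name}",
            f"parameters:       {count_parameters(self.model):,}",
            f"epochs trained:   {self.epochs_trained}",
            f"stop reason:      {self.stop_reason}",
            f"best {self.config.monitor} loss:    {self.best_loss:.4f} "
            f"(epoch {self.best_epoch})",
            f"final lr:         {h['lr'].iloc[-1]:.2e}",
            f"plateau events:   {int(h['plateau'].sum())}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
def _epoch_loss(model, pairs, batch_size, sigma, classes):
    losses, weights = [], []
    order = np.arange(len(pairs))
    for x, masks in _to_batches(pairs, order, batch_size):
        probs = model.forward(x, training=False)
        losses.append(soft_loss(probs, masks, classes, sigma).item())
        weights.append(len(x))
    return float(np.average(losses, weights=weights))


def train(model, train_set, val_set, config=None, classes=DEFAULT_CLASSES,
          callback=None):
    """Fit a segmentation model on sparse-labeled patches.

    train_set / val_set are sequences of (image HWC in [0,1], scribble
    mask) pairs or benchmark patches.  Returns a :class:`TrainingResult`
    whose history logs per-epoch train/validation loss, learning rate
    and plateau events.
    """
    config = config or TrainingConfig()
    train_pairs = [_as_pair(p) for p in train_set]
    val_pairs = [_as_pair(p) for p in val_set]
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be nonempty")

    opt = Adam(model.parameters(), lr=config.learning_rate)
    sched = PlateauSchedule(
        config.learning_rate, config.patience, config.lr_factor,
        config.max_plateaus, config.min_delta,
    )
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    dropout_rng = np.random.default_rng(config.shuffle_seed + 1)

    rows = []
    best_loss, best_epoch, best_state = np.inf, 0, None
    stop_reason = "max_epochs"
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_pairs))
        batch_losses, batch_sizes = [], []
        for x, masks in _to_batches(train_pairs, order, config.batch_size):
            probs = model.forward(x, training=True, rng=dropout_rng)
            loss = soft_loss(probs, masks, classes, config.sigma)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"nonfinite training loss at epoch {epoch} "
                    f"(batch starting with patch {order[0]})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(loss.item())
            batch_sizes.append(len(x))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        val_loss = _epoch_loss(model, val_pairs, config.batch_size,
                               config.sigma, classes)
        monitored = val_loss if config.monitor == "val" else train_loss
        plateau, stop = sched.step(monitored)
        opt.lr = sched.lr
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "lr": sched.lr, "plateau": plateau}
        )
        if monitored < best_loss:
            best_loss, best_epoch = monitored, epoch
            best_state = model.state_dict()
        if callback is not None:
            callback(epoch, rows[-1])
        if stop:
            stop_reason = f"{config.max_plateaus} consecutive plateaus"
            break

    return TrainingResult(
        model=model, config=config, history=pd.DataFrame(rows),
        best_epoch=best_epoch, best_loss=float(best_loss),
        best_state=best_state, stop_reason=stop_reason,
    )


# --------------------------------------------------------------------------
# evaluation helpers
# --------------------------------------------------------------------------
def evaluate(model, patches, classes=DEFAULT_CLASSES, sigma=DEFAULT_SIGMA,
             labels="dense"):
    """Pooled evaluation over patches carrying dense truth (or scribbles).

    Counts are pooled over the whole set (micro per class), then reported
    per class and as unweighted macro means, together with one-vs-rest
    ROC/AUC.
    """
    pooled = None
    all_probs, all_labels = [], []
    for p in patches:
        truth = getattr(p, labels) if not isinstance(p, tuple) else p[1]
        image = p.image if not isinstance(p, tuple) else p[0]
        probs = model.predict(image)
        conf = confusion_counts(probs, truth, classes, sigma, mode="hard")
        pooled = conf if pooled is None else pooled + conf
        all_probs.append(probs.reshape(-1, probs.shape[-1]))
        all_labels.append(np.asarray(truth).reshape(-1))
    metrics = compute_metrics(pooled)
    roc = roc_auc(np.concatenate(all_probs), np.concatenate(all_labels), classes)
    return {"confusion": pooled, "metrics": metrics, "roc": roc}


# --------------------------------------------------------------------------
# hyperparameter grid
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class GridSpec:
    batch_sizes: tuple = (1, 2, 4, 8, 16, 32)
    dropouts: tuple = (0.0, 0.125, 0.25, 0.375)
    learning_rates: tuple = (1e-2, 1e-3, 1e-4)
    attention_options: tuple = (False, True)
    residual_options: tuple = (False, True)
    recurrent_options: tuple = (False, True)

    def combinations(self):
        """Deterministic enumeration of the full Cartesian product."""
        return list(
            itertools.product(
                self.batch_sizes, self.dropouts, self.learning_rates,
                self.attention_options, self.residual_options,
                self.recurrent_options,
            )
        )


@dataclass(frozen=True)
class GridBudget:
    """Desk-scale resource cap applied to every grid cell."""

    max_epochs: int = 3
    levels: int = 2
    base_width: int = 8
    recurrence_steps: int = 2
    subset: int = 0  # take only the first N training patches; 0 = all


def run_grid(space, train_set, val_set, budget=None, base_config=None,
             results_path=None):
    """Train one model per hyperparameter combination; returns a table.

    Partial failures are recorded per row.  If ``results_path`` names an
    existing CSV from an earlier run, finished combinations are skipped
    (resumability).
    """
    budget = budget or GridBudget()
    done = {}
    if results_path is not None:
        try:
            prev = pd.read_csv(results_path)
            done = {r["combo"]: r for _, r in prev.iterrows()}
        except (OSError, pd.errors.EmptyDataError):
            pass
    if budget.subset:
        train_set = list(train_set)[: budget.subset]
    rows = []
    for combo_id, (bs, drop, lr, attn, res, rec) in enumerate(space.combinations()):
        combo = f"bs{bs}-do{drop}-lr{lr:g}-a{int(attn)}r{int(res)}q{int(rec)}"
        if combo in done:
            rows.append(dict(done[combo]))
            continue
        arch = ArchitectureConfig(
            levels=budget.levels, base_width=budget.base_width,
            attention=attn, residual=res, recurrent=rec,
            recurrence_steps=budget.recurrence_steps, dropout_rate=drop,
        )
        tcfg = TrainingConfig(
            batch_size=bs, learning_rate=lr, max_epochs=budget.max_epochs,
        )
        row = {"combo": combo, "batch_size": bs, "dropout": drop, "lr": lr,
               "attention": attn, "residual": res, "recurrent": rec}
        try:
            model = build_model(arch, seed=tcfg.init_seed)
            result = train(model, train_set, val_set, tcfg)
            row.update(
                best_val_loss=result.best_loss,
                epochs=result.epochs_trained, error="",
            )
        except Exception as exc:  # recorded per row, not fatal
            row.update(best_val_loss=np.nan, epochs=0, error=str(exc))
        rows.append(row)
        if results_path is not None:
            pd.DataFrame(rows).to_csv(results_path, index=False)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ablation report
# --------------------------------------------------------------------------
def ablation_report(trained, eval_set, classes=DEFAULT_CLASSES):
    """Mean +/- sd metric table across replicates, per network variant.

    ``trained`` maps variant name -> list of TrainingResult replicates.
    Returns (metrics table, per-class AUC table) as DataFrames.
    """
    metric_rows, auc_rows = [], []
    for name, results in trained.items():
        if not results:
            raise ValueError(f"variant {name!r} has no trained replicates")
        per_rep = {m: [] for m in ("precision", "recall", "specificity", "dice")}
        aucs = []
        for result in results:
            ev = evaluate(result.restore_best(), eval_set, classes)
            macro = ev["metrics"].macro()
            for m in per_rep:
                per_rep[m].append(macro[m])
            aucs.append(ev["roc"])
        model = results[0].model
        row = {"variant": name}
        for m, vals in per_rep.items():
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sd"] = float(np.std(vals, ddof=0))
        row["parameters"] = count_parameters(model)
        row["epochs_mean"] = float(np.mean([r.epochs_trained for r in results]))
        row["dropout"] = model.config.dropout_rate
        metric_rows.append(row)
        arow = {"variant": name}
        for c in classes:
            vals = [r.auc[c] for r in aucs if c in r.auc]
            arow[f"auc_class_{c}"] = float(np.mean(vals)) if vals else np.nan
        arow["auc_macro"] = float(np.mean([r.macro_auc for r in aucs]))
        auc_rows.append(arow)
    return pd.DataFrame(metric_rows), pd.DataFrame(auc_rows)


# --------------------------------------------------------------------------
# hard-example mining
# --------------------------------------------------------------------------
def rank_hard_examples(model, patches, classes=DEFAULT_CLASSES,
                       sigma=DEFAULT_SIGMA):
    """Sort labeled patches by descending per-patch sparse loss.

    Returns a DataFrame (id, loss) — the front of the list is what an
    annotator should inspect and relabel next.  Ties keep id order.
    """
    rows = []
    for i, p in enumerate(patches):
        image, mask = _as_pair(p)
        pid = getattr(p, "id", i)
        probs = model.predict(image)
        conf = confusion_counts(probs, mask, classes, sigma, mode="soft")
        present = [k for k in range(len(classes))
                   if conf.tp[k] + conf.fn[k] > 0]  # classes scribbled here
        if present:
            sub = dataclasses.replace(
                conf,
                tp=conf.tp[present], fp=conf.fp[present],
                fn=conf.fn[present], tn=conf.tn[present],
                classes=tuple(classes[k] for k in present),
            )
            loss = harmonic_mean_loss(sub).loss
        else:
            loss = 0.0
        rows.append({"id": pid, "loss": float(loss)})
    df = pd.DataFrame(rows)
    return df.sort_values(["loss", "id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
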