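"""Five-fold cross-validated training: optimizer, LR schedule, fold making.

Training follows a fixed recipe: voxels are sampled once per fold
(class-rebalanced, see :mod:`mvseg.patch_sampling`), then each epoch is one
pass over the sampled voxels in shuffled batches of 512, minimizing the batch
soft-dice loss with Adam.  The learning rate starts at 1e-3 and is lowered by
20% after every fifth epoch; 25 epochs per fold by default.  Folds are
stratified on (tumor-volume group x location) so their composition stays
comparable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence as Seq

import numpy as np

from mvseg.evaluation import volume_group
from mvseg.inference import predicted_volume_cm3
from mvseg.mvcnn import MVCNN, ModelConfig, build_model
from mvseg.patch_sampling import extract_batch, prepare_case_stack, sample_voxels
from mvseg.volume_io import LabelMask, MultiSequenceCase


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    epochs: int = 25
    batch_size: int = 512
    lr0: float = 1e-3
    lr_decay: float = 0.8
    decay_every: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    tumor_frac: float = 0.5
    healthy_frac: float = 0.01
    seed: int = 0
    folds: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")


@dataclass
class FoldSplit:
    """Partition of case ids over folds, with the strata used to balance it."""

    assignments: dict[str, int]
    strata: dict[str, str]
    k: int

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(cid for cid, f in self.assignments.items() if f == fold)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a 0-based epoch: ``lr0 * decay^floor(epoch/5)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= cfg.epochs:
        raise ValueError(f"epoch {epoch} out of range for {cfg.epochs}-epoch schedule")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.decay_every)


def make_folds(cases: Seq[MultiSequenceCase], k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold assignment on (volume group x location).

    Within every stratum the cases are shuffled and dealt round-robin starting
    from a random fold, so fold sizes within a stratum differ by at most one.
    """
    if k > len(cases):
        raise ValueError(f"cannot split {len(cases)} cases into {k} folds")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = defaultdict(list)
    stratum_of: dict[str, str] = {}
    for case in sorted(cases, key=lambda c: c.case_id):
        vg = volume_group(predicted_volume_cm3(case.reference)).name
        s = f"{vg}|{case.location.value}"
        strata[s].append(case.case_id)
        stratum_of[case.case_id] = s
    assignments: dict[str, int] = {}
    for s in sorted(strata):
        ids = strata[s]
        rng.shuffle(ids)
        start = int(rng.integers(k))
        for i, cid in enumerate(ids):
            assignments[cid] = (start + i) % k
    return FoldSplit(assignments=assignments, strata=stratum_of, k=k)


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1**self.t
        bias2 = 1.0 - c.beta2**self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            params[k] -= (lr * mhat / (np.sqrt(vhat) + c.adam_eps)).astype(params[k].dtype)


def build_training_set(
    cases: Seq[MultiSequenceCase],
    body_mask: LabelMask,
    cfg: TrainConfig,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Sample voxels for every case and precompute padded channel stacks.

    Returns (per-case stacks, rows (N, 4) of [case_idx, i, j, k], labels (N,)).
    """
    stacks: list[np.ndarray] = []
    rows: list[list[int]] = []
    labels: list[int] = []
    for ci, case in enumerate(cases):
        stacks.append(prepare_case_stack(case, body_mask))
        samples = sample_voxels(
            case.reference,
            body_mask,
            tumor_frac=cfg.tumor_frac,
            healthy_frac=cfg.healthy_frac,
            seed=cfg.seed * 100003 + ci,
            case_id=case.case_id,
        )
        for s in samples:
            rows.append([ci, *s.index])
            labels.append(s.label)
    return stacks, np.asarray(rows, dtype=np.intp), np.asarray(labels, dtype=np.int8)


def train_fold(
    train_cases: Seq[MultiSequenceCase],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    body_mask: LabelMask,
    model: Optional[MVCNN] = None,
) -> tuple[MVCNN, list[float]]:
    """Train one model on the given cases.

    One epoch is a full pass over the pre-sampled voxels in shuffled batches
    (last partial batch kept).  Returns the trained model and the per-epoch
    mean loss history.  Fully reproducible under fixed seeds.
    """
    if len(train_cases) == 0:
        raise ValueError("empty training set")
    stacks, rows, labels = build_training_set(train_cases, body_mask, cfg)
    if model is None:
        model = build_model(model_cfg, seed=cfg.seed)
    opt = Adam(model.params, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[float] = []
    n = len(rows)
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = _gather_batch(stacks, rows[sel])
            loss, grads = model.train_step_grads(batch, labels[sel])
            opt.step(model.params, grads, lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def _gather_batch(stacks: list[np.ndarray], rows: np.ndarray) -> np.ndarray:
    """Extract patch sets for rows [case_idx, i, j, k] spanning several cases."""
    out = np.empty((len(rows), 6, 32, 32, 3), dtype=np.float32)
    for ci in np.unique(rows[:, 0]):
        sel = rows[:, 0] == ci
        out[sel] = extract_batch(stacks[ci], rows[sel, 1:])
    return out


def cross_validate(
    cases: Seq[MultiSequenceCase],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    body_mask: LabelMask,
    folds: Optional[FoldSplit] = None,
) -> list[tuple[MVCNN, list[str], list[float]]]:
    """k-fold cross-validation.

    For each fold, trains on all cases outside it and returns
    ``(model, held_out_case_ids, loss_history)``.  Every case is held out
    exactly once; a held-out case never influences the model evaluated on it.
    """
    if folds is None:
        folds = make_folds(cases, cfg.folds, cfg.seed)
    by_id = {c.case_id: c for c in cases}
    out = []
    for f in range(folds.k):
        held = folds.fold_cases(f)
        train_ids = [cid for cid in sorted(by_id) if folds.assignments[cid] != f]
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 7919 * (f + 1)})
        model, history = train_fold(
            [by_id[cid] for cid in train_ids], fold_cfg, model_cfg, body_mask
        )
        out.append((model, held, history))
    return out
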