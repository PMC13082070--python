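"""Pre-training loop: data splitting, LR schedule, AdamW, validation.

The schedule is linear warmup from zero to the peak rate over the first
3,000 steps followed by a half-period cosine decay to the minimum rate
(10% of peak) at the final step, constant thereafter. The optimizer is
AdamW with no weight decay and no gradient clipping.

Defaults mirror the full-scale recipe (peak 4.0e-4, 250k steps, batch
1024); `TrainConfig.desk()` gives a profile sized for CPU-scale tests.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from idiomkit.fim import DEFAULT_VOCAB, TokenSequence
from idiomkit.model import DecoderLM, next_token_loss, Params


@dataclass
class TrainConfig:
    peak_lr: float = 4.0e-4
    min_lr: float = 4.0e-5
    warmup_steps: int = 3000
    total_steps: int = 250_000
    batch_size: int = 1024
    weight_decay: float = 0.0
    val_every: int = 25_000
    split_fracs: Tuple[float, float, float] = (0.99, 0.005, 0.005)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_lr > self.peak_lr:
            raise ValueError("min_lr must not exceed peak_lr")
        if not self.warmup_steps < self.total_steps:
            raise ValueError("warmup_steps must be below total_steps")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def desk(cls, total_steps: int = 500, seed: int = 0) -> "TrainConfig":
        """CPU-scale profile: small batch, short warmup, frequent validation."""
        return cls(
            peak_lr=3e-3,
            min_lr=3e-4,
            warmup_steps=max(1, total_steps // 10),
            total_steps=total_steps,
            batch_size=32,
            val_every=max(1, total_steps // 5),
            seed=seed,
        )


def split_dataset(
    n_records: int,
    fracs: Sequence[float] = (0.99, 0.005, 0.005),
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets.

    Sizes are within one record of ``n * frac`` (the final set absorbs the
    rounding remainder); the three sets partition ``{0..n-1}`` and are
    deterministic under the seed.
    """
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n_records < 3:
        raise ValueError("need at least 3 records to split three ways")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_records)
    n_train = round(n_records * fracs[0])
    n_val = round(n_records * fracs[1])
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Learning rate at an optimizer step (0-indexed ramp, continuous join)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step <= cfg.warmup_steps:
        return cfg.peak_lr * (step / cfg.warmup_steps)
    if step >= cfg.total_steps:
        return cfg.min_lr
    progress = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
    return cfg.min_lr + 0.5 * (cfg.peak_lr - cfg.min_lr) * (
        1.0 + math.cos(math.pi * progress)
    )


class AdamW:
    """AdamW in NumPy; decoupled weight decay (zero by default here)."""

    def __init__(
        self,
        params: Params,
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Params, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if self.weight_decay:
                p -= lr * self.weight_decay * p
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_id_matrix(corpus: Sequence[TokenSequence]) -> np.ndarray:
    width = max(len(s.ids) for s in corpus)
    pad = DEFAULT_VOCAB.pad_id
    out = np.full((len(corpus), width), pad, dtype=np.int64)
    for i, s in enumerate(corpus):
        out[i, : len(s.ids)] = s.ids
    return out


def _eval_loss(model: DecoderLM, ids: np.ndarray, ignore: List[int]) -> float:
    logits = model.forward(ids)
    return float(next_token_loss(logits[:, :-1], ids[:, 1:], ignore))


def pretrain(
    model: DecoderLM,
    corpus: Sequence[TokenSequence],
    cfg: TrainConfig,
    checkpoint_dir: Optional[str | Path] = None,
    max_width: Optional[int] = None,
) -> Dict[str, list]:
    """Train a model autoregressively on an encoded corpus.

    The corpus is split 99/0.5/0.5 by default, shuffled each epoch with a
    seeded generator, and batched; the loss is next-token cross-entropy
    ignoring pad (and reserved mask) targets. Returns a history dict with
    per-step train loss and periodic validation loss; optionally writes
    checkpoints at validation points and at the end.

    ``max_width`` trims the padded batch matrix to a fixed width (the
    longest sequence is never trimmed below its true length).

    Batching is length-bucketed: sequences are sorted by length, cut into
    contiguous batches, and the batch order is shuffled each epoch with a
    seeded generator. Each batch is trimmed to its own longest sequence,
    so attention cost tracks typical rather than maximal length; the run
    stays deterministic under the seed.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    vocab = DEFAULT_VOCAB
    ignore = [vocab.pad_id, vocab.mask_id]
    ids_all = _as_id_matrix(corpus)
    if max_width is not None and ids_all.shape[1] > max_width:
        true_max = max(s.length for s in corpus)
        ids_all = ids_all[:, : max(max_width, true_max)]
    lengths = np.array([s.length for s in corpus])

    if len(corpus) >= 3:
        tr_idx, val_idx, _ = split_dataset(len(corpus), cfg.split_fracs, cfg.seed)
        if len(val_idx) == 0:
            val_idx = tr_idx[: min(32, len(tr_idx))]
    else:
        tr_idx = np.arange(len(corpus))
        val_idx = tr_idx
    val_ids = ids_all[val_idx[:256]]
    val_ids = val_ids[:, : max(int(lengths[val_idx[:256]].max()), 2)]

    opt = AdamW(model.params, lr=cfg.peak_lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history: Dict[str, list] = {"step": [], "lr": [], "train_loss": [],
                                "val_step": [], "val_loss": []}
    by_len = tr_idx[np.argsort(lengths[tr_idx], kind="stable")]
    batches = [
        by_len[i : i + cfg.batch_size] for i in range(0, len(by_len), cfg.batch_size)
    ]
    order = rng.permutation(len(batches))
    cursor = 0
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for step in range(1, cfg.total_steps + 1):
        if cursor >= len(order):
            order = rng.permutation(len(batches))
            cursor = 0
        sel = batches[order[cursor]]
        cursor += 1
        batch = ids_all[sel][:, : max(int(lengths[sel].max()), 2)]
        logits, cache = model.forward(batch, want_cache=True)
        loss, dlogits = next_token_loss(
            logits[:, :-1], batch[:, 1:], ignore, return_grad=True
        )
        full_d = np.zeros_like(logits)
        full_d[:, :-1] = dlogits
        grads = model.backward(full_d, cache)
        opt.step(grads, lr=lr_schedule(step, cfg))
        history["step"].append(step)
        history["lr"].append(lr_schedule(step, cfg))
        history["train_loss"].append(float(loss))
        if step % cfg.val_every == 0 or step == cfg.total_steps:
            vloss = _eval_loss(model, val_ids, ignore)
            history["val_step"].append(step)
            history["val_loss"].append(vloss)
            if ckpt_dir:
                model.save(ckpt_dir / f"step{step:08d}")
    if ckpt_dir:
        model.save(ckpt_dir / "final")
    return history


def write_history_csv(history: Dict[str, list], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "lr", "train_loss"])
        for s, lr, tl in zip(history["step"], history["lr"], history["train_loss"]):
            w.writerow([s, lr, tl])
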