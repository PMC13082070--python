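"""Desk-scale experiment recipes.

End-to-end protocols sized for one CPU: pre-train a tiny two-layer model
on a synthetic IDR corpus, then align it with GRPO against a single
quadratic reward term (length or compositional entropy). These are the
canonical scaled-down study conditions used by the test suite and the
reproduction script; the functions return everything needed to evaluate
the outcome (the aligned model, the metric traces, and a sample of
sequences from the final checkpoint).

Problem sizes: 2,000 training sequences, a 2-layer / 4-head / width-64
model (~0.17M parameters), 300 pre-training steps at the desk schedule,
400 GRPO steps with group size 8 and 8 prompts per step at learning rate
2e-4 (the full-scale post-training rate of 5e-6 is matched to a model
three orders of magnitude larger), and 500 sequences sampled from the
final checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from idiomkit.curation import IdrRecord
from idiomkit.fim import encode_corpus
from idiomkit.fixtures import CorpusSpec, synth_idr_corpus
from idiomkit.model import DecoderLM, ModelConfig
from idiomkit.rl import GrpoConfig, RewardSpec, grpo_train
from idiomkit.sampler import GenerationRequest, generate_many
from idiomkit.trainer import TrainConfig, pretrain

TINY_MODEL = dict(n_layers=2, n_heads=4, d_model=64, max_len=160, dtype="float32")

#: low-entropy composition (about 2.2 nats per sequence on average),
#: used when the entropy reward must pull diversity upward
LOW_ENTROPY_COMPOSITION = {
    "G": 0.30, "S": 0.25, "P": 0.15, "E": 0.12, "K": 0.08,
    "A": 0.05, "D": 0.03, "T": 0.02,
}


@dataclass
class DeskRun:
    """Everything a scaled-down pre-train + GRPO run produced."""

    model: DecoderLM
    history: Dict[str, List[float]]
    samples: List[str]

    @property
    def mean_length(self) -> float:
        return float(np.mean([len(s) for s in self.samples]))

    @property
    def mean_entropy(self) -> float:
        from idiomkit.rl import sequence_entropy

        return float(np.mean([sequence_entropy(s) for s in self.samples if s]))

    @property
    def max_kl(self) -> float:
        return float(max(self.history["kl"]))


def make_desk_corpus(
    kind: str = "median60", n: int = 2000, seed: int = 0
) -> List[IdrRecord]:
    """Synthetic IDP corpus: ``median60`` (length study) or ``low_entropy``."""
    if kind == "median60":
        spec = CorpusSpec(n_sequences=n, median_length=60.0, max_length=150, seed=seed)
    elif kind == "low_entropy":
        spec = CorpusSpec(
            n_sequences=n, median_length=60.0, max_length=150,
            composition=LOW_ENTROPY_COMPOSITION, seed=seed,
        )
    else:
        raise ValueError(f"unknown corpus kind {kind!r}")
    seqs = synth_idr_corpus(spec)
    return [IdrRecord(f"s{i}", "", s, "", 1, len(s)) for i, s in enumerate(seqs)]


def pretrain_tiny(
    records: List[IdrRecord], seed: int = 0, steps: int = 300
) -> DecoderLM:
    """Pre-train the tiny reference model on an IDP corpus."""
    corpus = encode_corpus(records, max_len=TINY_MODEL["max_len"])
    model = DecoderLM(ModelConfig(**TINY_MODEL), seed=seed)
    pretrain(model, corpus, TrainConfig.desk(total_steps=steps, seed=seed))
    return model


def grpo_reward_run(
    reward: str,
    seed: int = 0,
    steps: int = 400,
    n_samples: int = 500,
    pretrain_steps: int = 300,
    model: Optional[DecoderLM] = None,
) -> DeskRun:
    """Pre-train (unless a model is supplied) and align with a single reward.

    ``reward`` is ``"length"`` (quadratic penalty around 100 residues, on a
    corpus of median length 60) or ``"entropy"`` (quadratic penalty around
    2.7 nats, on a low-entropy corpus). Sampling from the final checkpoint
    uses the same generation cap as training.
    """
    if reward == "length":
        spec = RewardSpec(w_score=0.0, w_entropy=0.0)
        corpus_kind = "median60"
    elif reward == "entropy":
        spec = RewardSpec(w_score=0.0, w_length=0.0)
        corpus_kind = "low_entropy"
    else:
        raise ValueError(f"unknown reward {reward!r}")
    if model is None:
        model = pretrain_tiny(
            make_desk_corpus(corpus_kind, seed=seed), seed=seed, steps=pretrain_steps
        )
    cfg = GrpoConfig.desk(steps=steps)
    history = grpo_train(model, cfg, spec, score_model=lambda s: 0.5, seed=seed)
    req = GenerationRequest(max_len=cfg.gen_max_len, seed=seed + 1)
    samples = generate_many(model, req, n_samples)
    return DeskRun(model=model, history=history, samples=samples)
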