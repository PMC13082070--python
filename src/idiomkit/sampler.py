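"""Autoregressive decoding in prompted (FIM) and unprompted (IDP) modes.

At each step the next token is drawn from softmax(z_t / T) over the full
vocabulary, at temperature T = 1.0 by default. Generation stops on <eos>
or when the total token count (prompt included) reaches ``max_len``.

Structural and control tokens other than <eos> (<N>, <C>, <I>, <bos>,
<pad>, <mask>) are masked to -inf during decoding, so emitted sequences
are pure residue strings terminated by <eos>; importance ratios and KL
estimates computed downstream use this same masked, renormalized
distribution, which is the distribution actually sampled from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from idiomkit.fim import CANONICAL_AA, DEFAULT_VOCAB, TokenSequence, Vocabulary
from idiomkit.model import DecoderLM


@dataclass
class GenerationRequest:
    mode: str = "unprompted"  # "prompted" | "unprompted"
    n_context: str = ""
    c_context: str = ""
    temperature: float = 1.0
    max_len: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("prompted", "unprompted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for ctx in (self.n_context, self.c_context):
            if any(ch not in CANONICAL_AA for ch in ctx):
                raise ValueError("contexts must be canonical residues")


def build_prompt(req: GenerationRequest, vocab: Vocabulary = DEFAULT_VOCAB) -> TokenSequence:
    """FIM prompt: <bos><N>{n_ctx}<C>{c_ctx}<I> (contexts empty when unprompted)."""
    n_ctx = req.n_context if req.mode == "prompted" else ""
    c_ctx = req.c_context if req.mode == "prompted" else ""
    ids = (
        [vocab.bos_id, vocab["<N>"]]
        + [vocab.token_to_id[a] for a in n_ctx]
        + [vocab["<C>"]]
        + [vocab.token_to_id[a] for a in c_ctx]
        + [vocab.idr_id]
    )
    if len(ids) >= req.max_len:
        raise ValueError(
            f"prompt of {len(ids)} tokens leaves no room under max_len={req.max_len}"
        )
    return TokenSequence(ids=ids, prompt_len=len(ids), length=len(ids))


def sample_tokens(
    model: DecoderLM,
    prompt_ids: Sequence[int],
    n: int,
    temperature: float = 1.0,
    max_len: int = 512,
    seed: int = 0,
    vocab: Vocabulary = DEFAULT_VOCAB,
    suppress_eos: bool = False,
    return_logprobs: bool = False,
) -> Tuple[List[List[int]], List[List[float]]]:
    """Sample ``n`` completions of a shared prompt in one batched pass.

    Returns per-sequence completion token ids (with the terminating <eos>
    excluded) and, when requested, the log-probability of each sampled
    token under the masked softmax(z/T) distribution — including the
    log-probability of the terminating <eos> draw, so that importance
    weights cover the stopping decision.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    prompt_ids = list(prompt_ids)
    budget = max_len - len(prompt_ids)
    if budget <= 0:
        raise ValueError("prompt already at max_len")
    rng = np.random.default_rng(seed)
    forbidden = [i for i in vocab.special_ids if i != vocab.eos_id]
    if suppress_eos:
        forbidden = list(vocab.special_ids)

    kv = model.init_kv_cache(n, max_len)
    logits = None
    for tok in prompt_ids:
        logits = model.step(np.full(n, tok, dtype=np.int64), kv)

    completions: List[List[int]] = [[] for _ in range(n)]
    logprobs: List[List[float]] = [[] for _ in range(n)]
    active = np.ones(n, dtype=bool)
    for _ in range(budget):
        z = logits / temperature
        z[:, forbidden] = -np.inf
        z -= z.max(-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(-1, keepdims=True)
        u = rng.random(n)
        choice = (np.cumsum(p, axis=-1) < u[:, None]).sum(-1)
        choice = np.minimum(choice, p.shape[-1] - 1)
        logp = np.log(p[np.arange(n), choice])
        for i in range(n):
            if not active[i]:
                continue
            if return_logprobs:
                logprobs[i].append(float(logp[i]))
            if choice[i] == vocab.eos_id:
                active[i] = False
            else:
                completions[i].append(int(choice[i]))
        if not active.any():
            break
        # finished rows keep stepping with <pad>; their draws are discarded
        step_ids = np.where(active, choice, vocab.pad_id).astype(np.int64)
        logits = model.step(step_ids, kv)
    return completions, logprobs


def generate_many(
    model: DecoderLM,
    req: GenerationRequest,
    n: int,
    vocab: Vocabulary = DEFAULT_VOCAB,
    suppress_eos: bool = False,
) -> List[str]:
    """Sample ``n`` amino-acid strings for one request (batched, seeded)."""
    prompt = build_prompt(req, vocab)
    completions, _ = sample_tokens(
        model,
        prompt.ids,
        n,
        temperature=req.temperature,
        max_len=req.max_len,
        seed=req.seed,
        vocab=vocab,
        suppress_eos=suppress_eos,
    )
    return ["".join(vocab.id_to_token[i] for i in seq) for seq in completions]


def generate(
    model: DecoderLM,
    req: GenerationRequest,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> str:
    """Sample a single sequence; deterministic under the request seed."""
    return generate_many(model, req, 1, vocab)[0]


def write_fasta(seqs: Sequence[str], path, req: Optional[GenerationRequest] = None) -> None:
    mode = req.mode if req else "unprompted"
    seed = req.seed if req else 0
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">gen_{i} mode={mode} seed={seed}\n{s}\n")
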