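"""GRPO post-training against a pluggable reward model.

Group Relative Policy Optimization samples a group of completions per
prompt, scores each with a composite reward, and uses the within-group
z-scored rewards as advantages — no learned value function. The loss is a
PPO-style clipped importance-weighted policy-gradient term plus a KL
penalty that tethers the policy to the frozen pre-trained reference.

The composite reward is a sum of quadratic penalties around three targets:
a reward-model score (default target 0.9), the sequence length (default
target 100 residues, normalized by a 100-residue scale so the three terms
are commensurate), and the per-sequence Shannon entropy of amino-acid
composition (default target 2.7 nats, which guards against diversity
collapse). The reward model is any callable mapping an amino-acid string
to a probability; a deterministic toy localization score with documented
logistic coefficients ships for desk-scale runs, and an external scorer
can be plugged in via a line-protocol subprocess.

The KL penalty direction is KL(reference || policy), estimated per sampled
completion token with an unbiased low-variance estimator; the conventional
KL(policy || reference) direction is available via a switch. Loss
aggregation is token-level across the batch (normalize by the total number
of completion tokens) following the DAPO convention, switchable to
per-sequence averaging. Prompt tokens never contribute to the loss.
"""

from __future__ import annotations

import math
import subprocess
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from idiomkit.fim import CANONICAL_AA, DEFAULT_VOCAB, Vocabulary
from idiomkit.model import DecoderLM, Params
from idiomkit.sampler import GenerationRequest, build_prompt, sample_tokens
from idiomkit.trainer import AdamW

ScoreModel = Callable[[str], float]


@dataclass
class RewardSpec:
    """Targets and weights of the composite quadratic reward.

    The reward is maximal (zero) exactly when the score, length and
    entropy all sit at their targets; each term can be switched off by
    zeroing its weight. ``length_scale`` divides the length deviation so
    an unnormalized (L-100)^2 does not dwarf the other terms.
    """

    target_score: float = 0.9
    target_length: float = 100.0
    target_entropy: float = 2.7
    w_score: float = 1.0
    w_length: float = 1.0
    w_entropy: float = 1.0
    length_scale: float = 100.0

    def __post_init__(self) -> None:
        if min(self.w_score, self.w_length, self.w_entropy) < 0:
            raise ValueError("weights must be nonnegative")
        if not (0 < self.target_entropy <= math.log(20) + 1e-12):
            raise ValueError("target entropy must lie in (0, ln 20]")


@dataclass
class GrpoConfig:
    group_size: int = 8
    clip: float = 0.2
    kl_weight: float = 0.02
    lr: float = 5e-6
    batch_prompts: int = 8
    steps: int = 1500
    gen_max_len: int = 512
    temperature: float = 1.0
    kl_direction: str = "ref_current"  # as printed; or "current_ref"
    token_level: bool = True  # DAPO-style aggregation across the batch
    exact_kl: bool = False  # full-vocabulary KL per position (debug)

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group size must be >= 2")
        if not 0 < self.clip < 1:
            raise ValueError("clip must be in (0, 1)")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")
        if self.kl_direction not in ("ref_current", "current_ref"):
            raise ValueError("kl_direction must be 'ref_current' or 'current_ref'")

    @classmethod
    def desk(cls, steps: int = 400, lr: float = 2e-4, gen_max_len: int = 160) -> "GrpoConfig":
        """CPU-scale profile: shorter context and a learning rate sized for
        tiny (two-layer, width-64) policies."""
        return cls(steps=steps, lr=lr, gen_max_len=gen_max_len)


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (nats) of the within-sequence residue composition."""
    if len(seq) == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def composite_reward(seq: str, score: float, spec: RewardSpec) -> float:
    """Sum of quadratic penalties around the score/length/entropy targets.

    Empty sequences take entropy 0 (the homopolymer limit) rather than
    raising, so degenerate rollouts during RL still receive a well-defined
    (strongly negative) reward.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    h = sequence_entropy(seq) if seq else 0.0
    r = -spec.w_score * (score - spec.target_score) ** 2
    r -= spec.w_length * ((len(seq) - spec.target_length) / spec.length_scale) ** 2
    r -= spec.w_entropy * (h - spec.target_entropy) ** 2
    return r


def group_advantages(rewards: Sequence[float], eps: float = 1e-8) -> np.ndarray:
    """Within-group z-scores (population sd); all-equal groups give zeros."""
    r = np.asarray(rewards, dtype=float)
    if r.size < 2:
        raise ValueError("need a group of at least 2")
    return (r - r.mean()) / (r.std() + eps)


# fixed, documented coefficients of the toy localization score:
# logit = -3.0 + 8.0 * frac(K,R) + 4.0 * frac(G) + 0.5 * count(RGG)
_TOY_INTERCEPT = -3.0
_TOY_W_KR = 8.0
_TOY_W_G = 4.0
_TOY_W_RGG = 0.5


def toy_localization_reward(seq: str) -> float:
    """Deterministic stand-in scorer for desk-scale RL experiments.

    A logistic function of interpretable composition features associated
    with nucleolar/granule localization: the basic-residue (K+R) fraction,
    the glycine fraction, and the number of RGG tripeptides. Output is a
    probability in [0, 1].
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if any(ch not in CANONICAL_AA for ch in seq):
        raise ValueError("non-canonical residue")
    n = len(seq)
    f_kr = sum(1 for ch in seq if ch in "KR") / n
    f_g = seq.count("G") / n
    n_rgg = sum(1 for i in range(n - 2) if seq[i : i + 3] == "RGG")
    logit = _TOY_INTERCEPT + _TOY_W_KR * f_kr + _TOY_W_G * f_g + _TOY_W_RGG * n_rgg
    return 1.0 / (1.0 + math.exp(-logit))


class SubprocessScoreModel:
    """Line-protocol wrapper: write a sequence, read back a probability.

    Lets an external scorer (e.g. a neural localization predictor) be
    plugged in without code changes: the executable reads one amino-acid
    string per line on stdin and prints one float in [0, 1] per line.
    """

    def __init__(self, command: Sequence[str]):
        self.proc = subprocess.Popen(
            list(command),
            stdin=subprocess.PIPE,
            stdout=subprocess.PIPE,
            text=True,
            bufsize=1,
        )

    def __call__(self, seq: str) -> float:
        assert self.proc.stdin and self.proc.stdout
        self.proc.stdin.write(seq + "\n")
        self.proc.stdin.flush()
        return float(self.proc.stdout.readline())

    def close(self) -> None:
        if self.proc.stdin:
            self.proc.stdin.close()
        self.proc.wait(timeout=10)


def _masked_log_softmax(logits: np.ndarray, forbidden: Sequence[int]) -> np.ndarray:
    z = logits.copy()
    z[..., list(forbidden)] = -np.inf
    m = z.max(-1, keepdims=True)
    e = np.exp(z - m)
    return z - m - np.log(e.sum(-1, keepdims=True))


def grpo_update(
    policy: DecoderLM,
    reference: DecoderLM,
    prompts: Sequence[Sequence[int]],
    cfg: GrpoConfig,
    spec: RewardSpec,
    score_model: ScoreModel,
    opt: AdamW,
    seed: int = 0,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> Dict[str, float]:
    """One GRPO optimizer step over a batch of prompts.

    Per prompt, ``group_size`` completions are sampled from the current
    policy (their per-token log-probabilities are recorded as the old
    policy); rewards are scored, advantages z-scored within each group,
    and a single clipped policy-gradient + KL-penalty step is taken.
    Returns step metrics: mean reward, mean completion length (residues),
    the per-token KL estimate, the loss and the gradient norm.
    """
    G = cfg.group_size
    forbidden = [i for i in vocab.special_ids if i != vocab.eos_id]
    rng = np.random.default_rng(seed)

    # sample G completions per prompt; identical prompts share one batched call
    comp_all: List[List[int]] = []
    lps_all: List[List[float]] = []
    if all(list(p) == list(prompts[0]) for p in prompts):
        comp_all, lps_all = sample_tokens(
            policy, prompts[0], G * len(prompts),
            temperature=cfg.temperature, max_len=cfg.gen_max_len,
            seed=int(rng.integers(2**31)), vocab=vocab, return_logprobs=True,
        )
    else:
        for prompt_ids in prompts:
            c, l = sample_tokens(
                policy, prompt_ids, G,
                temperature=cfg.temperature, max_len=cfg.gen_max_len,
                seed=int(rng.integers(2**31)), vocab=vocab, return_logprobs=True,
            )
            comp_all.extend(c)
            lps_all.extend(l)

    seqs_tok: List[List[int]] = []
    old_lp: List[List[float]] = []
    prompt_lens: List[int] = []
    advantages: List[float] = []
    rewards_all: List[float] = []
    for gi, prompt_ids in enumerate(prompts):
        comp = comp_all[gi * G : (gi + 1) * G]
        lps = lps_all[gi * G : (gi + 1) * G]
        group_rewards = []
        for c in comp:
            s = "".join(vocab.id_to_token[i] for i in c)
            try:
                score = score_model(s) if s else 0.0
            except Exception as exc:  # noqa: BLE001 - diagnostic per contract
                raise RuntimeError(f"score model failed on {s[:30]!r}...: {exc}") from exc
            group_rewards.append(composite_reward(s, score, spec))
        adv = group_advantages(group_rewards)
        for c, lp, a, r in zip(comp, lps, adv, group_rewards):
            full = list(prompt_ids) + c
            if len(lp) > len(c):  # an <eos> was drawn and logged
                full = full + [vocab.eos_id]
            seqs_tok.append(full)
            old_lp.append(lp)
            prompt_lens.append(len(prompt_ids))
            advantages.append(float(a))
            rewards_all.append(r)

    B = len(seqs_tok)
    n_tokens_total = sum(len(lp) for lp in old_lp)
    if n_tokens_total == 0:
        return {
            "mean_reward": float(np.mean(rewards_all)),
            "mean_length": 0.0,
            "kl": 0.0,
            "loss": 0.0,
            "grad_norm": 0.0,
        }

    # process in length-sorted buckets so attention cost tracks typical length;
    # gradients accumulate across buckets, then a single optimizer step is taken
    bucket_size = 16
    by_len = sorted(range(B), key=lambda i: len(seqs_tok[i]))
    grads: Optional[Params] = None
    pg_sum = 0.0
    kl_sum = 0.0
    for b0 in range(0, B, bucket_size):
        sel = by_len[b0 : b0 + bucket_size]
        width = max(len(seqs_tok[i]) for i in sel)
        ids = np.full((len(sel), width), vocab.pad_id, dtype=np.int64)
        for bi, i in enumerate(sel):
            ids[bi, : len(seqs_tok[i])] = seqs_tok[i]

        logits, cache = policy.forward(ids, want_cache=True)
        ref_logits = reference.forward(ids)
        logp_all = _masked_log_softmax(
            logits.astype(np.float64) / cfg.temperature, forbidden)
        ref_logp_all = _masked_log_softmax(
            ref_logits.astype(np.float64) / cfg.temperature, forbidden)
        dlogits = np.zeros_like(logits)

        for bi, i in enumerate(sel):
            lp_old, P = old_lp[i], prompt_lens[i]
            n_t = len(lp_old)
            if n_t == 0:
                continue
            cols = np.arange(P, P + n_t)  # target token columns
            toks = ids[bi, cols]
            rows = cols - 1  # logit rows that score those targets
            lp_new = logp_all[bi, rows, toks]
            lp_ref = ref_logp_all[bi, rows, toks]
            lp_old_a = np.asarray(lp_old, dtype=np.float64)

            denom = n_tokens_total if cfg.token_level else (B * n_t)
            A = advantages[i]
            rho = np.exp(lp_new - lp_old_a)
            unclipped = rho * A
            clipped = np.clip(rho, 1 - cfg.clip, 1 + cfg.clip) * A
            obj = np.minimum(unclipped, clipped)
            pg_sum += -obj.sum() / denom
            active = unclipped <= clipped  # gradient only when unclipped is the min
            dlp = -(A * rho) * active / denom

            if cfg.exact_kl:
                dlp_kl = np.zeros_like(dlp)
                # -inf log-probs on masked tokens carry zero mass; make the
                # subtraction safe before weighting by the probabilities
                cur_lp = np.where(np.isfinite(logp_all[bi, rows]),
                                  logp_all[bi, rows], 0.0)
                ref_lp = np.where(np.isfinite(ref_logp_all[bi, rows]),
                                  ref_logp_all[bi, rows], 0.0)
                p_cur_all = np.exp(logp_all[bi, rows])
                p_ref_all = np.exp(ref_logp_all[bi, rows])
                if cfg.kl_direction == "ref_current":
                    kl_t = (p_ref_all * (ref_lp - cur_lp)).sum(-1)
                    for r_idx, row in enumerate(rows):
                        g_row = -p_ref_all[r_idx] / denom * cfg.kl_weight
                        dlogits[bi, row] += (
                            g_row - p_cur_all[r_idx] * g_row.sum()
                        ) / cfg.temperature
                else:
                    kl_t = (p_cur_all * (cur_lp - ref_lp)).sum(-1)
                    for r_idx, row in enumerate(rows):
                        pc = p_cur_all[r_idx]
                        integrand = np.where(pc > 0, cur_lp[r_idx] - ref_lp[r_idx] + 1.0, 0.0)
                        g_row = cfg.kl_weight / denom * pc * integrand
                        dlogits[bi, row] += (g_row - pc * g_row.sum()) / cfg.temperature
                kl_sum += float(kl_t.sum())
            else:
                r = np.exp(lp_ref - lp_new)
                if cfg.kl_direction == "ref_current":
                    k_t = r * np.log(r) - (r - 1.0)
                    dk = -r * np.log(r)
                else:
                    k_t = (r - 1.0) - np.log(r)
                    dk = 1.0 - r
                kl_sum += float(k_t.sum())
                dlp_kl = cfg.kl_weight * dk / denom

            g = dlp + dlp_kl  # d(loss)/d(lp_new), per token
            probs = np.exp(logp_all[bi, rows])  # masked softmax probabilities
            contrib = g[:, None] * (-probs)
            contrib[np.arange(n_t), toks] += g
            dlogits[bi, rows] += contrib / cfg.temperature

        bucket_grads = policy.backward(dlogits, cache)
        if grads is None:
            grads = bucket_grads
        else:
            for k in grads:
                grads[k] += bucket_grads[k]

    assert grads is not None
    grad_norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    opt.step(grads, lr=cfg.lr)

    kl_per_token = kl_sum / n_tokens_total
    loss = pg_sum + cfg.kl_weight * kl_per_token
    # completion length counts residues only (the <eos>, when present, is excluded)
    mean_len = float(
        np.mean(
            [
                sum(1 for t in s[P:] if t != vocab.eos_id)
                for s, P in zip(seqs_tok, prompt_lens)
            ]
        )
    )
    return {
        "mean_reward": float(np.mean(rewards_all)),
        "mean_length": mean_len,
        "kl": float(kl_per_token),
        "loss": float(loss),
        "grad_norm": grad_norm,
    }


def grpo_train(
    policy: DecoderLM,
    cfg: GrpoConfig,
    spec: RewardSpec,
    score_model: ScoreModel,
    seed: int = 0,
    reference: Optional[DecoderLM] = None,
    request: Optional[GenerationRequest] = None,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> Dict[str, List[float]]:
    """Run GRPO for ``cfg.steps`` optimizer steps; mutates ``policy``.

    The reference defaults to a frozen copy of the initial policy. Prompts
    default to the unprompted IDP prompt <bos><N><C><I>, repeated
    ``batch_prompts`` times per step. Returns per-step metric traces.
    """
    if reference is None:
        reference = policy.clone()
    req = request or GenerationRequest(mode="unprompted", max_len=cfg.gen_max_len)
    prompt = build_prompt(req, vocab)
    prompts = [prompt.ids] * cfg.batch_prompts
    opt = AdamW(policy.params, lr=cfg.lr)
    rng = np.random.default_rng(seed)
    history: Dict[str, List[float]] = {
        "step": [], "mean_reward": [], "mean_length": [], "kl": [],
        "loss": [], "grad_norm": [],
    }
    for step in range(1, cfg.steps + 1):
        m = grpo_update(
            policy, reference, prompts, cfg, spec, score_model, opt,
            seed=int(rng.integers(2**31)), vocab=vocab,
        )
        history["step"].append(step)
        for k in ("mean_reward", "mean_length", "kl", "loss", "grad_norm"):
            history[k].append(m[k])
    return history


def write_metrics_csv(history: Dict[str, List[float]], path) -> None:
    import csv

    keys = list(history.keys())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(keys)
        for row in zip(*(history[k] for k in keys)):
            w.writerow(row)
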