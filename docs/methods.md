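# Methods

This note documents the models and procedures implemented in `idiomkit`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## IDR curation from pLDDT traces

Per-residue pLDDT confidence is smoothed with a centered moving average
(window 15, odd). At the termini the window shrinks to what fits inside
the trace rather than padding with invented values, so every smoothed
score is a mean of real scores in [0, 100]. Classification is by strict
inequalities — smoothed score > 80 folded, < 70 disordered — and a score
exactly at either threshold falls into the gap band, the only assignment
consistent with both strict rules.

Refinement is a single pass in a fixed order: (1) maximal runs are
formed; (2) folded/disordered runs shorter than 10 residues are demoted
to gaps; (3) adjacent gaps merge; (4) a gap flanked by two disordered
runs, or terminal and adjacent to a disordered run, becomes disordered;
(5) every other gap — including a gap between one disordered and one
folded neighbour — becomes folded; (6) same-label neighbours merge. The
result contains no gaps, tiles the protein, and is a fixed point of the
procedure (re-running it changes nothing), which the tests assert on
random label strings. Gap merging happens before relabeling; no further
iteration is performed.

Records are dropped when the IDR is shorter than 30 residues, the protein
exceeds 512 residues, the protein is entirely disordered, or the sequence
contains a residue outside the canonical 20 (X, B, Z, U, O, J have no
token, so the whole protein is skipped). Flanking contexts are the entire
remainder of the protein on each side; other IDRs inside a flank are kept
as plain sequence. Coordinates are 0-based half-open internally and
1-based inclusive on disk.

## Tokenization and the fill-in-the-middle transform

The alphabet has exactly 27 tokens. `<mask>` is reserved — present in the
vocabulary, never emitted — because training is purely causal. Encoding
frames the FIM string with `<bos>`/`<eos>` and pads to 512. Because the
curation cap (512 residues) plus the five framing/sentinel tokens can
exceed the 512-token context, corpus building rejects over-length items
rather than truncating them: truncation would sever the `<I>` span and
silently corrupt the training signal. The effective residue budget is
therefore 507.

Loss masking covers pad (and the reserved mask) targets only; sentinel
and context tokens do contribute to the loss, since training is plain
next-token prediction over the whole transformed sequence.

## Transformer core

A decoder-only pre-LayerNorm transformer: per block, LayerNorm →
multi-head causal attention (rotary position embeddings applied to the
full head dimension, base 10,000) → residual, then LayerNorm → SwiGLU
feedforward (three matrices: gate, up, down) → residual; a final
LayerNorm feeds an untied linear head. No biases on attention or
feedforward projections; LayerNorms carry scale and shift. The
feedforward hidden width is `ratio × d_model` rounded to the nearest
multiple of 64.

The implementation is NumPy end to end, with the backward pass derived by
hand and verified against central finite differences to relative error
below 1e-4 on every parameter family. Default precision is float64;
desk-scale training profiles use float32, which halves memory traffic.
Incremental decoding uses a key/value cache and matches the full forward
pass to 1e-10.

At the full configuration (12 layers, 14 heads, width 896, ratio 8/3,
vocabulary 27, untied head) the exact trainable count is **115,010,560**
(feedforward hidden width 2368). The nominal figure quoted for this
architecture is 122M; no rounding convention of the 8/3 ratio we tried
reproduces it exactly (ceiling to a multiple of 64 gives 117.0M), so the
count is reported as computed, with a per-group breakdown available from
`count_parameters(model, breakdown=True)`, rather than tuning widths to
hit a printed number.

## Pre-training

AdamW (β = 0.9/0.999), no weight decay, no gradient clipping. The
schedule ramps linearly from zero to the peak rate over the warmup
(origin at zero is the common convention; the ramp's end point is exact),
then follows a half-period cosine to 10% of peak at the final step, and
is constant afterwards. Data are split 99 / 0.5 / 0.5 with a seeded
permutation. Batches are length-bucketed: sequences are sorted by length,
cut into contiguous batches, the batch order is reshuffled each epoch
with the seeded generator, and each batch is trimmed to its longest
member. This keeps attention cost proportional to typical rather than
maximal length and is exactly reproducible under the seed, at the price
of correlating batch contents by length — immaterial at desk scale and
testable (fixed seed reproduces the loss curve bit for bit).

Desk profile (`TrainConfig.desk`): peak 3e-3, batch 32, warmup one tenth
of the run. The full-scale defaults (peak 4e-4, batch 1024, 250k steps)
are retained as the standard profile but are not exercised by the tests.

## Generation

Sampling draws from the full categorical `softmax(z_t / T)` at T = 1.
Sentinel and control tokens other than `<eos>` are masked to −∞ at every
step: emitted sequences are then pure residue strings, which is the only
way the outputs can be parsed downstream. This masking is an
interpretation — the decoding rules do not say how mid-stream structural
tokens are handled — and all log-probabilities used by reinforcement
learning (policy, old policy, reference) are computed under the same
masked, renormalized distribution, which is the distribution actually
sampled from, so importance ratios remain exact. `max_len` counts the
full token sequence including the prompt; with `<eos>` suppressed,
generation stops at exactly 512 total tokens.

## GRPO post-training

Per step, 8 prompts × group size 8 completions are sampled from the
current policy; their per-token log-probabilities are recorded at
sampling time and serve as the old policy (single inner epoch, so the
importance ratio starts at 1 and the clipped term is exact). Rewards are
the composite quadratic; advantages are within-group z-scores with a
population standard deviation and an 1e-8 floor (an all-equal group gives
zero advantages, not NaNs). The loss is token-level across the batch
(normalized by the total number of completion tokens, the aggregation
usually attributed to DAPO; per-sequence averaging is a switch). Prompt
tokens are excluded everywhere. The `<eos>` draw is part of the
completion: its log-probability is logged and it contributes a loss
token, so the stopping decision itself is optimized.

The KL penalty is applied in the direction KL(reference ‖ policy), as
specified for this recipe; the conventional direction is a switch. It is
estimated per sampled token by the unbiased non-negative estimator
`r log r − (r − 1)` with `r = p_ref/p_policy` (expectation under the
policy equals the reference-first KL); an exact full-vocabulary
per-position KL is available as a debug mode, and the two agree in scale
on drifted policies in the tests. The reward of an empty completion uses
entropy 0 (the homopolymer limit) so degenerate rollouts are penalized
rather than crashing.

Scaled-down study conditions (`idiomkit.experiments`): 2,000 synthetic
sequences, a 2-layer / 4-head / width-64 model (~0.17M parameters,
float32, context 160), 300 pre-training steps, 400 GRPO steps at learning
rate 2e-4. The full-scale post-training rate (5e-6) pairs with a model
three orders of magnitude larger; 2e-4 is the corresponding desk-scale
choice and is fixed in the recipe. The length study pre-trains on a
corpus of median length 60 and aligns with the length-only reward; the
entropy study pre-trains on a deliberately low-entropy composition
(~1.7 nats mean) and aligns with the entropy-only reward. Outcomes are
scored on 500 sequences sampled from the final checkpoint. The test suite
runs the same protocol at 200 steps (the runs plateau near step 120);
the reproduction script runs the full 400.

## Sequence analytics

Charges: K/R = +1, D/E = −1, histidine and cysteine neutral (pH-7
convention); the table is a parameter. κ follows the blob-variance
construction with windows {5, 6} averaged. The normalizer δ_max is the
largest δ over all *maximally segregated* arrangements of the same
composition — each charge sign one contiguous block, the neutral residues
split into at most three runs around and between the blocks, all
placements scanned (exhaustively up to 40 neutrals, by coarse grid plus
local refinement beyond). The naive "charge blocks at the two ends,
neutrals in the middle" normalizer is *not* maximal — exhaustive
enumeration at n = 12 finds interior-block arrangements with δ up to
1.75× larger, which would push κ above 1 — and the scanned construction
matches the exhaustive maximum over all charge placements in every
composition tested. κ is undefined (NaN) for chargeless sequences and
when δ_max = 0.

SHD uses Kyte–Doolittle hydropathy rescaled linearly to [0, 1]; the scale
is a named, swappable table. Complexity is mean windowed Shannon entropy
(window 12, base 2; shorter sequences use one whole-sequence window) —
the compositional criterion of low-complexity detection, not the full
Wootton–Federhen trimming algorithm. Composition enrichment pools counts
over residues (length-weighted), not per-sequence means. The normalized
Wasserstein-1 distance divides the empirical W1 (scipy) by the standard
deviation of the reference sample by default; the normalizer is an
explicit argument since no convention is universal.

Motif patterns ship as an editable TSV (classic monopartite/bipartite
NLS, a documented subset of modification-site consensi, RGG/RG, [FY]GG,
SYG). They are approximate defaults, data rather than code. Scanning
re-anchors at every position so overlapping sites are all reported;
co-occurrence asks whether two match starts lie within 30 residues
(inclusive).

## Synthetic data

The protein generator draws residues from label-appropriate compositions
and pLDDT per residue from the label's Gaussian (folded 92 ± 3,
disordered 55 ± 6), clipped to [0, 100], with linear ramps (4 residues)
across boundaries. Clipping rather than truncated-normal resampling is
deliberate and documented. The corpus generator samples lengths from a
log-normal (median 80 by default, clipped to [30, 300]) and residues
i.i.d. from a disorder-biased composition (P, S, G, E, K enriched;
hydrophobics and aromatics depleted — the directionality of real IDR
composition bias without claiming its magnitudes). The charge-blockiness
dial rearranges charged residues at their sampled positions — fully
segregated blocks versus strict alternation — preserving composition
exactly, so κ separates the two regimes while FCR does not.

None of the generators emulate the spatial autocorrelation of real
AlphaFold confidence, real folded domains, or real IDR grammar. Passing
tests therefore demonstrate that the algorithms are implemented correctly
under controlled ground truth, not that the model generates biologically
realistic disordered sequences.

## Known limitations

* Desk scale only: the full 12-layer configuration instantiates and
  counts correctly but is not trained here; no mixed precision, no
  distributed training.
* The parameter count at the stated architecture is 115.0M against a
  nominal 122M; the discrepancy is documented rather than resolved.
* Sequence clustering (MMseqs2) is out of scope; for reference, the
  upstream corpus was clustered with
  `mmseqs linclust --min-seq-id 0.9 --cov-mode 0 -c 0.8 --cluster-mode 2`.
* The shipped reward model is a deterministic logistic toy; real
  localization predictors plug in via the callable contract or the
  line-protocol subprocess.
* Motif regexes are approximate stand-ins for a curated resource.
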