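"""Fill-in-the-middle tokenization for IDR records.

The alphabet has exactly 27 symbols: the 20 canonical amino acids, three
structural sentinels (``<N>`` for the N-terminal flanking context, ``<C>``
for the C-terminal flanking context, ``<I>`` for the IDR span itself) and
four control tokens (``<bos>``, ``<eos>``, ``<pad>``, ``<mask>``).
``<mask>`` is reserved: it is a member of the vocabulary but is never
emitted by any operation here, since training is purely causal.

A curated IDR record is rearranged into fill-in-the-middle (FIM) order

    <N> n_context <C> c_context <I> idr

so that a causal model conditions on both flanks before generating the
disordered span. Removing both flanks (the "IDP augmentation") yields the
degenerate prompt ``<N><C><I>`` followed by the bare disordered sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, List, Sequence

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues with no representation in the alphabet; their presence anywhere
#: in a protein disqualifies it at curation time
NONCANONICAL_AA = set("XBZUOJ")

BOS, EOS, PAD, MASK = "<bos>", "<eos>", "<pad>", "<mask>"
N_CTX, C_CTX, IDR_TOK = "<N>", "<C>", "<I>"

_SPECIALS = (BOS, EOS, PAD, MASK, N_CTX, C_CTX, IDR_TOK)


class Vocabulary:
    """The fixed 27-token alphabet with dense integer ids.

    Token order is frozen (controls, sentinels, then the amino acids in
    alphabetical order) so that ids are stable across runs; `to_json` /
    `from_json` serialize the order explicitly for checkpoint side-cars.
    """

    def __init__(self, tokens: Sequence[str] | None = None):
        if tokens is None:
            tokens = list(_SPECIALS) + list(CANONICAL_AA)
        self.tokens: List[str] = list(tokens)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        if len(self.tokens) != 27:
            raise ValueError(f"the alphabet has exactly 27 tokens, got {len(self.tokens)}")
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        self.id_to_token = {i: t for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id[token]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def idr_id(self) -> int:
        return self.token_to_id[IDR_TOK]

    @property
    def amino_acid_ids(self) -> List[int]:
        return [self.token_to_id[a] for a in CANONICAL_AA]

    @property
    def special_ids(self) -> List[int]:
        return [self.token_to_id[t] for t in _SPECIALS]

    def to_json(self) -> str:
        return json.dumps(self.tokens)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(json.loads(text))


#: module-level default vocabulary; every operation uses it unless another
#: Vocabulary is passed explicitly
DEFAULT_VOCAB = Vocabulary()


def tokenize(text: str) -> List[str]:
    """Split a token string into tokens (angle-bracket specials or residues)."""
    out: List[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "<":
            j = text.find(">", i)
            if j < 0:
                raise ValueError(f"unterminated special token at position {i}")
            tok = text[i : j + 1]
            if tok not in DEFAULT_VOCAB.token_to_id:
                raise ValueError(f"unknown special token {tok!r}")
            out.append(tok)
            i = j + 1
        else:
            if ch not in CANONICAL_AA:
                raise ValueError(f"unknown residue {ch!r} at position {i}")
            out.append(ch)
            i += 1
    return out


@dataclass
class TokenSequence:
    """Encoded token ids plus the prompt/completion boundary.

    ``prompt_len`` is the index of the first completion token, i.e. one
    past the ``<I>`` sentinel; ``length`` is the attention-relevant length
    (everything before padding, including ``<bos>`` and ``<eos>``).
    """

    ids: List[int]
    prompt_len: int
    length: int

    def __post_init__(self) -> None:
        ids = self.ids
        vocab = DEFAULT_VOCAB
        if not ids or ids[0] != vocab.bos_id:
            raise ValueError("token sequence must start with <bos>")
        if ids.count(vocab.idr_id) != 1:
            raise ValueError("token sequence must contain exactly one <I>")
        if ids.count(vocab.eos_id) > 1:
            raise ValueError("at most one <eos> allowed")
        if not (0 < self.prompt_len <= self.length <= len(ids)):
            raise ValueError("inconsistent prompt_len / length")


def fim_transform(record) -> str:
    """Rearrange an IDR record into fill-in-the-middle token-string order.

    Returns ``<N> + n_context + <C> + c_context + <I> + idr``. Raises on
    non-canonical residues, which the alphabet cannot represent.
    """
    for part in (record.n_context, record.idr, record.c_context):
        for ch in part:
            if ch not in CANONICAL_AA:
                raise ValueError(f"non-canonical residue {ch!r}")
    return N_CTX + record.n_context + C_CTX + record.c_context + IDR_TOK + record.idr


def fim_invert(text: str):
    """Recover (n_context, c_context, idr) from a FIM token string."""
    if not text.startswith(N_CTX):
        raise ValueError("missing <N> sentinel")
    body = text[len(N_CTX) :]
    n_ctx, _, rest = body.partition(C_CTX)
    c_ctx, sep, idr = rest.partition(IDR_TOK)
    if not sep:
        raise ValueError("missing <I> sentinel")
    return n_ctx, c_ctx, idr


def idp_augment(record):
    """Strip both flanking contexts, turning an IDR record into an IDP one.

    Returns a copy; the input record is left untouched. Coordinates are
    preserved so provenance within the source protein is not lost.
    """
    return replace(record, n_context="", c_context="")


def augment_corpus(records: Iterable) -> Iterator:
    """Yield each record followed by its context-free duplicate (2n total)."""
    for rec in records:
        yield rec
        yield idp_augment(rec)


def encode(
    text: str,
    max_len: int = 512,
    vocab: Vocabulary = DEFAULT_VOCAB,
    pad: bool = True,
) -> TokenSequence:
    """Encode a FIM token string to padded ids with <bos>/<eos> framing.

    The tokenized length including <bos> and <eos> must not exceed
    ``max_len``; longer items are rejected (truncation would destroy the
    ``<I>`` span, so corpus builds drop them instead).
    """
    toks = tokenize(text)
    ids = [vocab.bos_id] + [vocab.token_to_id[t] for t in toks] + [vocab.eos_id]
    if len(ids) > max_len:
        raise ValueError(f"sequence of {len(ids)} tokens exceeds max_len={max_len}")
    length = len(ids)
    try:
        prompt_len = ids.index(vocab.idr_id) + 1
    except ValueError:
        raise ValueError("encoded sequence lacks the <I> sentinel") from None
    if pad:
        ids = ids + [vocab.pad_id] * (max_len - len(ids))
    return TokenSequence(ids=ids, prompt_len=prompt_len, length=length)


def decode(seq: TokenSequence | Sequence[int], vocab: Vocabulary = DEFAULT_VOCAB) -> str:
    """Invert `encode`: strip <bos>/<eos>/<pad> framing, keep the FIM body."""
    ids = seq.ids if isinstance(seq, TokenSequence) else list(seq)
    out: List[str] = []
    for i in ids:
        tok = vocab.id_to_token[i]
        if tok == PAD or tok == BOS:
            continue
        if tok == EOS:
            break
        out.append(tok)
    return "".join(out)


def encode_corpus(
    records: Iterable,
    max_len: int = 512,
    idp_augmented: bool = False,
) -> List[TokenSequence]:
    """Encode a record iterable, silently dropping over-length items."""
    stream = augment_corpus(records) if idp_augmented else records
    out: List[TokenSequence] = []
    for rec in stream:
        try:
            out.append(encode(fim_transform(rec), max_len=max_len))
        except ValueError:
            continue
    return out
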