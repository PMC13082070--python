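"""Seeded synthetic-data generators.

Three generators back the desk-scale pipeline end to end:

* proteins with segment-structured pLDDT traces (folded segments high and
  confident, disordered segments low and noisier, linear ramps across the
  boundaries) together with their ground-truth segmentation, for testing
  the curation rules;
* IDR corpora with a controllable length distribution (log-normal, median
  80, clipped to [30, 300] — short disordered regions dominate real
  curated sets, with a tail out to a few hundred residues), a
  disorder-biased residue composition (P, S, G, E, K enriched; the
  order-promoting hydrophobics and aromatics depleted) and a
  charge-blockiness dial ``b`` that interpolates between strictly
  alternating charge placement (b=0) and fully segregated charge blocks
  (b=1);
* the scrambled-sequence null: a uniform random permutation of a sequence,
  which preserves composition exactly (hence FCR and compositional
  entropy) while destroying order-dependent patterning such as kappa.

Everything is bit-reproducible under a fixed seed. These generators make
no attempt to emulate the spatial autocorrelation of real AlphaFold
confidence traces or the structure of real folded domains; they provide
controlled ground truth, not biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from idiomkit.curation import Label, PlddtTrace, Segment
from idiomkit.fim import CANONICAL_AA

#: disorder-biased residue frequencies (P,S,G,E,K up; L,I,V,F,W,Y,C down)
DISORDER_COMPOSITION: Dict[str, float] = {
    "A": 0.06, "C": 0.005, "D": 0.055, "E": 0.095, "F": 0.015,
    "G": 0.10, "H": 0.02, "I": 0.02, "K": 0.08, "L": 0.04,
    "M": 0.015, "N": 0.04, "P": 0.11, "Q": 0.05, "R": 0.055,
    "S": 0.13, "T": 0.06, "V": 0.03, "W": 0.005, "Y": 0.015,
}

#: folded-domain-like composition (hydrophobics enriched)
FOLDED_COMPOSITION: Dict[str, float] = {
    "A": 0.09, "C": 0.02, "D": 0.05, "E": 0.06, "F": 0.045,
    "G": 0.06, "H": 0.02, "I": 0.06, "K": 0.06, "L": 0.11,
    "M": 0.02, "N": 0.04, "P": 0.04, "Q": 0.035, "R": 0.05,
    "S": 0.06, "T": 0.055, "V": 0.075, "W": 0.015, "Y": 0.035,
}


@dataclass
class SegmentLayout:
    """Ground-truth layout of a synthetic protein.

    ``segments`` is an ordered list of (label, length) pairs; pLDDT is
    drawn per residue from the label's Gaussian (folded 92 +/- 3,
    disordered 55 +/- 6 by default), clipped to [0, 100], with linear
    ramps of ``ramp`` residues across each boundary.
    """

    segments: List[Tuple[str, int]]
    folded_mean: float = 92.0
    folded_sd: float = 3.0
    disordered_mean: float = 55.0
    disordered_sd: float = 6.0
    ramp: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for label, length in self.segments:
            if label not in ("FOLDED", "DISORDERED"):
                raise ValueError(f"bad label {label!r}")
            if length < 1:
                raise ValueError("segment lengths must be >= 1")
        for m in (self.folded_mean, self.disordered_mean):
            if not 0 <= m <= 100:
                raise ValueError("means must lie in [0, 100]")


def synth_protein_with_plddt(
    layout: SegmentLayout, protein_id: str = "synth"
) -> Tuple[PlddtTrace, List[Segment]]:
    """Synthesize a protein and its pLDDT trace from a segment layout.

    Residues are drawn from a label-appropriate composition; the returned
    ground-truth segments use the curation module's Segment type so
    recovery tests compare like with like.
    """
    rng = np.random.default_rng(layout.seed)
    seq_parts: List[str] = []
    means: List[float] = []
    sds: List[float] = []
    truth: List[Segment] = []
    pos = 0
    for label, length in layout.segments:
        comp = FOLDED_COMPOSITION if label == "FOLDED" else DISORDER_COMPOSITION
        aas = list(comp.keys())
        probs = np.array(list(comp.values()))
        probs = probs / probs.sum()
        seq_parts.append("".join(rng.choice(aas, size=length, p=probs)))
        mu = layout.folded_mean if label == "FOLDED" else layout.disordered_mean
        sd = layout.folded_sd if label == "FOLDED" else layout.disordered_sd
        means.extend([mu] * length)
        sds.extend([sd] * length)
        truth.append(Segment(pos, pos + length, Label(label)))
        pos += length

    mean_arr = np.asarray(means, dtype=float)
    if layout.ramp > 0 and len(truth) > 1:
        mean_arr = _ramp_means(mean_arr, [s.end for s in truth[:-1]], layout.ramp)
    noise = rng.normal(0.0, 1.0, size=len(means)) * np.asarray(sds)
    plddt = np.clip(mean_arr + noise, 0.0, 100.0)
    trace = PlddtTrace(protein_id, "".join(seq_parts), plddt)
    return trace, truth


def _ramp_means(mean_arr: np.ndarray, boundaries: Sequence[int], ramp: int) -> np.ndarray:
    """Linear interpolation of the mean across each boundary (+/- ramp/2)."""
    out = mean_arr.copy()
    half = ramp // 2
    n = out.size
    for b in boundaries:
        lo, hi = max(b - half, 0), min(b + half, n)
        if hi - lo < 2:
            continue
        left = mean_arr[lo - 1] if lo > 0 else mean_arr[lo]
        right = mean_arr[hi] if hi < n else mean_arr[hi - 1]
        out[lo:hi] = np.linspace(left, right, hi - lo + 2)[1:-1]
    return out


@dataclass
class CorpusSpec:
    """Controls for the synthetic IDR corpus generator."""

    n_sequences: int = 1000
    median_length: float = 80.0
    length_sigma: float = 0.45  # log-normal shape
    min_length: int = 30
    max_length: int = 300
    composition: Optional[Dict[str, float]] = None
    charge_block: float = 0.0  # b: 0 alternating, 1 fully segregated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need n >= 1")
        if not 0.0 <= self.charge_block <= 1.0:
            raise ValueError("charge_block must lie in [0, 1]")
        comp = self.composition or DISORDER_COMPOSITION
        if abs(sum(comp.values()) - 1.0) > 1e-6:
            raise ValueError("composition must sum to 1")


def synth_idr_corpus(spec: CorpusSpec) -> List[str]:
    """Sample a corpus of disordered-like sequences.

    Lengths are log-normal with the requested median, clipped to
    [min_length, max_length]. Residue identities are drawn i.i.d. from the
    composition; the positions of charged residues are then rearranged
    according to the blockiness parameter ``b``: with probability ``b`` a
    sequence gets fully segregated charge blocks (all + together, all -
    together at opposite ends), otherwise its charges are placed in
    strictly alternating order at the originally charged positions.
    Composition is preserved exactly in both cases.
    """
    comp = spec.composition or DISORDER_COMPOSITION
    aas = list(comp.keys())
    probs = np.array(list(comp.values()))
    probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.median_length)
    seqs: List[str] = []
    for _ in range(spec.n_sequences):
        length = int(round(float(rng.lognormal(mu, spec.length_sigma))))
        length = int(np.clip(length, spec.min_length, spec.max_length))
        residues = list(rng.choice(aas, size=length, p=probs))
        blocky = rng.random() < spec.charge_block
        seqs.append(_arrange_charges(residues, blocky))
    return seqs


def _arrange_charges(residues: List[str], blocky: bool) -> str:
    """Rearrange charged residues at their positions: blocks or alternation."""
    pos_idx = [i for i, a in enumerate(residues) if a in "KR"]
    neg_idx = [i for i, a in enumerate(residues) if a in "DE"]
    charged_sites = sorted(pos_idx + neg_idx)
    pos_res = [residues[i] for i in pos_idx]
    neg_res = [residues[i] for i in neg_idx]
    if blocky:
        ordering = pos_res + neg_res
    else:
        ordering = []
        a, b = pos_res[:], neg_res[:]
        take_pos = True
        while a or b:
            if take_pos and a:
                ordering.append(a.pop(0))
            elif b:
                ordering.append(b.pop(0))
            elif a:
                ordering.append(a.pop(0))
            take_pos = not take_pos
    out = residues[:]
    for site, res in zip(charged_sites, ordering):
        out[site] = res
    return "".join(out)


def scramble(seq: str, seed: int = 0) -> str:
    """Uniform random permutation of the residues (composition preserved)."""
    if not seq:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    return "".join(rng.permutation(chars))


def plant_motifs(
    n_sequences: int,
    length: int,
    motif: str,
    rate: float,
    seed: int = 0,
    background: str = "ASTG",
) -> Tuple[List[str], List[List[Tuple[str, int]]]]:
    """Sequences with Poisson(rate)-planted copies of a literal motif.

    Returns the sequences and a per-sequence manifest of (motif, 1-based
    start) plants. The background alphabet excludes the motif's letters so
    no spurious copies arise; plants are placed on a non-overlapping grid.
    """
    bg = [c for c in background if c not in set(motif)]
    if not bg:
        raise ValueError("background overlaps motif alphabet")
    rng = np.random.default_rng(seed)
    k = len(motif)
    slots = length // k
    seqs: List[str] = []
    manifests: List[List[Tuple[str, int]]] = []
    for _ in range(n_sequences):
        chars = list(rng.choice(bg, size=length))
        n_plant = min(int(rng.poisson(rate)), slots)
        chosen = rng.choice(slots, size=n_plant, replace=False)
        manifest = []
        for slot in sorted(int(c) for c in chosen):
            start = slot * k
            chars[start : start + k] = list(motif)
            manifest.append((motif, start + 1))
        seqs.append("".join(chars))
        manifests.append(manifest)
    return seqs, manifests
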