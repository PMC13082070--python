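"""Sequence analytics for disordered regions.

Charge patterning (FCR, NCPR profiles, the kappa segregation parameter),
hydropathy clustering (SHD), compositional complexity (windowed Shannon
entropy), composition enrichment against a reference set, normalized
Wasserstein-1 distances between metric distributions, and short-linear-
motif scanning with co-occurrence rules.

Charge convention: lysine and arginine are +1, aspartate and glutamate are
-1, histidine and cysteine (and everything else) are neutral — the
standard pH-7 convention of the Das-Pappu charge-patterning literature.
The assignment is configurable where it matters.

kappa measures how far the linear arrangement of charges deviates from a
well-mixed one: blobs of size 5 and 6 are slid along the chain, the local
charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-) of each blob is compared
with the whole-sequence asymmetry, and the mean squared deviation delta is
normalized by the delta of the maximally segregated permutation of the
same composition. kappa near 0 means alternating/mixed charges; kappa = 1
means fully segregated charge blocks. Sequences with no charges (or whose
single charge sign makes the normalizer vanish) have undefined kappa,
reported as NaN.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from idiomkit.fim import CANONICAL_AA

# +1 for K/R, -1 for D/E, 0 otherwise (pH 7, histidine neutral)
DEFAULT_CHARGES: Dict[str, int] = {aa: 0 for aa in CANONICAL_AA}
DEFAULT_CHARGES.update({"K": 1, "R": 1, "D": -1, "E": -1})

# Kyte-Doolittle hydropathy, linearly rescaled from [-4.5, 4.5] to [0, 1]
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
HYDROPATHY_SCALES: Dict[str, Dict[str, float]] = {
    "kd_unit": {aa: (h + 4.5) / 9.0 for aa, h in _KYTE_DOOLITTLE.items()},
    "kd_raw": dict(_KYTE_DOOLITTLE),
}


def _charges(seq: str, charges: Dict[str, int] | None = None) -> np.ndarray:
    table = charges or DEFAULT_CHARGES
    try:
        return np.array([table[ch] for ch in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


def fcr(seq: str, charges: Dict[str, int] | None = None) -> float:
    """Fraction of charged residues (D, E, K, R by default)."""
    if not seq:
        raise ValueError("empty sequence")
    return float(np.count_nonzero(_charges(seq, charges))) / len(seq)


def ncpr_profile(
    seq: str, window: int = 5, charges: Dict[str, int] | None = None
) -> np.ndarray:
    """Sliding-window net charge per residue, truncated at the termini."""
    c = _charges(seq, charges)
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(([0.0], np.cumsum(c)))
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _window_sigma(c: np.ndarray, g: int) -> np.ndarray:
    """Charge asymmetry of every length-g window; chargeless windows give 0."""
    pos = np.convolve((c > 0).astype(float), np.ones(g), mode="valid") / g
    neg = np.convolve((c < 0).astype(float), np.ones(g), mode="valid") / g
    tot = pos + neg
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(tot > 0, (pos - neg) ** 2 / np.where(tot > 0, tot, 1.0), 0.0)
    return sigma


def _delta(c: np.ndarray, g: int) -> float:
    """Mean squared deviation of window asymmetry from global asymmetry."""
    fpos = float((c > 0).mean())
    fneg = float((c < 0).mean())
    tot = fpos + fneg
    sigma_seq = (fpos - fneg) ** 2 / tot if tot > 0 else 0.0
    sig = _window_sigma(c, g)
    return float(((sig - sigma_seq) ** 2).mean())


def _segregated(a: int, npos: int, b: int, nneg: int, c: int) -> np.ndarray:
    """Arrangement (0^a)(+^npos)(0^b)(-^nneg)(0^c)."""
    return np.array([0.0] * a + [1.0] * npos + [0.0] * b + [-1.0] * nneg + [0.0] * c)


@lru_cache(maxsize=4096)
def _delta_max(npos: int, nneg: int, nneu: int, g: int) -> float:
    """Largest delta over maximally segregated arrangements of a composition.

    Each charge sign forms one contiguous block; the neutral residues are
    split into (at most) three runs around and between the blocks, and all
    placements are scanned. Exhaustive when the neutral count is modest;
    for long sequences a coarse grid over the two free run lengths is
    refined locally, which recovers the optimum to within grid resolution.
    By symmetry (delta is invariant under reversal and global charge
    flip), scanning (a, b) with c determined covers the mirrors too.
    """

    def d(a: int, b: int) -> float:
        return _delta(_segregated(a, npos, b, nneg, nneu - a - b), g)

    if nneu <= 40:
        cand = [(a, b) for a in range(nneu + 1) for b in range(nneu - a + 1)]
        return max(d(a, b) for a, b in cand)
    # coarse grid, then +/- step local refinement around the best cell
    step = max(1, nneu // 24)
    grid = list(range(0, nneu + 1, step)) + [nneu]
    best, best_ab = -1.0, (0, 0)
    for a in grid:
        for b in grid:
            if a + b > nneu:
                continue
            v = d(a, b)
            if v > best:
                best, best_ab = v, (a, b)
    a0, b0 = best_ab
    for a in range(max(0, a0 - step), min(nneu, a0 + step) + 1):
        for b in range(max(0, b0 - step), min(nneu - a, b0 + step) + 1):
            v = d(a, b)
            if v > best:
                best = v
    return best


def kappa(
    seq: str,
    windows: Sequence[int] = (5, 6),
    charges: Dict[str, int] | None = None,
) -> float:
    """Charge-patterning parameter; NaN when undefined (no usable charges).

    delta is normalized by the delta of the maximally segregated
    arrangement of the same composition (contiguous charge blocks, neutral
    runs placed wherever delta is largest — see ``_delta_max``); the ratio
    delta/delta_max is averaged over the window sizes.
    """
    c = _charges(seq, charges)
    if len(seq) < max(windows):
        raise ValueError("sequence shorter than the largest window")
    if not np.any(c != 0):
        return float("nan")
    npos, nneg = int((c > 0).sum()), int((c < 0).sum())
    nneu = c.size - npos - nneg
    ratios = []
    for g in windows:
        dmax = _delta_max(npos, nneg, nneu, g)
        if dmax == 0.0:
            return float("nan")
        ratios.append(_delta(c, g) / dmax)
    return float(np.mean(ratios))


def shd(seq: str, scale: str = "kd_unit") -> float:
    """Sequence hydropathy decoration: (1/N) sum_{i<j} (h_i+h_j)/|j-i|.

    Distance-weighted pairwise hydropathy sum quantifying how clustered
    hydrophobic residues are along the chain. ``scale`` names a hydropathy
    table (default Kyte-Doolittle rescaled to [0, 1]).
    """
    if len(seq) < 2:
        raise ValueError("SHD needs at least 2 residues")
    table = HYDROPATHY_SCALES[scale]
    try:
        h = np.array([table[ch] for ch in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None
    n = h.size
    total = 0.0
    # O(n) per offset via vectorized shifts: sum over pairs at distance d
    for d in range(1, n):
        total += (h[:-d] + h[d:]).sum() / d
    return total / n


def seg_complexity(seq: str, window: int = 12) -> float:
    """Mean windowed compositional Shannon entropy in bits.

    Sequences shorter than the window are scored with a single
    whole-sequence window. Low values flag low-complexity regions, in the
    spirit of the SEG algorithm's compositional criterion.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < window:
        spans = [seq]
    else:
        spans = [seq[i : i + window] for i in range(len(seq) - window + 1)]
    ents = []
    for s in spans:
        n = len(s)
        counts = np.array(list(map(s.count, set(s))), dtype=float)
        p = counts / n
        ents.append(float(-(p * np.log2(p)).sum()))
    return float(np.mean(ents))


def composition(seq: str) -> np.ndarray:
    """Frequency vector over the 20 canonical residues (sums to 1)."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.array([seq.count(a) for a in CANONICAL_AA], dtype=float)
    return counts / counts.sum()


def composition_enrichment(
    seqs: Sequence[str], reference_seqs: Sequence[str]
) -> pd.Series:
    """Pooled per-residue frequency ratio of ``seqs`` over the reference.

    Frequencies are pooled over residues (weighted by sequence length),
    not averaged per sequence. A residue absent from the reference yields
    an infinite ratio (flagged, not an error); the neutral baseline is 1.
    """
    if not seqs or not reference_seqs:
        raise ValueError("both sequence sets must be non-empty")

    def pooled(ss: Sequence[str]) -> np.ndarray:
        joined = "".join(ss)
        c = np.array([joined.count(a) for a in CANONICAL_AA], dtype=float)
        return c / c.sum()

    f = pooled(seqs)
    ref = pooled(reference_seqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, f / np.where(ref > 0, ref, 1.0), np.inf)
        ratio = np.where((ref == 0) & (f == 0), np.nan, ratio)
    return pd.Series(ratio, index=list(CANONICAL_AA))


def wasserstein1(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    normalizer: Optional[float] = None,
) -> float:
    """Empirical 1-Wasserstein distance, divided by a normalizer.

    The default normalizer is the standard deviation of the second
    (reference) sample; pass ``normalizer=1.0`` for the raw distance.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if normalizer is None:
        normalizer = float(b.std())
    if normalizer == 0:
        raise ValueError("zero normalizer")
    return float(wasserstein_distance(a, b)) / normalizer


# ---------------------------------------------------------------------------
# motif scanning


@dataclass
class MotifPattern:
    """A named short-linear-motif regex with a class tag (NLS/MOD/RNA)."""

    name: str
    pattern: str
    tag: str

    def __post_init__(self) -> None:
        self.regex = re.compile(self.pattern)
        if self.tag not in ("NLS", "MOD", "RNA"):
            raise ValueError(f"unknown motif class {self.tag!r}")


def load_motif_patterns(path: str | Path | None = None) -> List[MotifPattern]:
    """Read patterns from a 3-column TSV (name, class, regex).

    Without a path, the packaged default table is used: classic
    monopartite/bipartite NLS regexes, a documented subset of ELM-style
    modification-site (MOD) patterns, and RGG/[FY]GG/SYG RNA-binding
    elements. The defaults are approximate, editable data — not code.
    """
    if path is None:
        src = resources.files("idiomkit.data").joinpath("motif_patterns.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    patterns: List[MotifPattern] = []
    seen = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, tag, rx = line.split("\t")
        if name in seen:
            raise ValueError(f"duplicate motif name {name!r}")
        seen.add(name)
        patterns.append(MotifPattern(name, rx, tag))
    return patterns


def motif_scan(
    seq: str, patterns: Sequence[MotifPattern]
) -> List[Tuple[str, int, int]]:
    """All (possibly overlapping) matches; coordinates 1-based inclusive.

    Overlap is found by re-anchoring the search at every position, since
    modification sites may legitimately overlap.
    """
    hits: List[Tuple[str, int, int]] = []
    for pat in patterns:
        for start in range(len(seq)):
            m = pat.regex.match(seq, start)
            if m and m.end() > m.start():
                hits.append((pat.name, start + 1, m.end()))
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def ptm_density(
    seqs: Sequence[str], mod_patterns: Sequence[MotifPattern]
) -> float:
    """Mean number of distinct (pattern, start) modification sites per sequence."""
    mods = [p for p in mod_patterns if p.tag == "MOD"]
    if not seqs:
        return 0.0
    total = 0
    for s in seqs:
        sites = {(name, start) for name, start, _ in motif_scan(s, mods)}
        total += len(sites)
    return total / len(seqs)


def motif_cooccurrence(
    seq: str, patterns: Sequence[MotifPattern], span: int = 30
) -> Tuple[bool, bool]:
    """(any match present, two matches with start positions <= span apart)."""
    if span < 1:
        raise ValueError("span must be >= 1")
    starts = sorted(start for _, start, _ in motif_scan(seq, patterns))
    present = len(starts) >= 1
    close = any(b - a <= span for a, b in zip(starts, starts[1:]))
    return present, close and len(starts) >= 2


# ---------------------------------------------------------------------------
# metric table


def metric_table(
    seqs: Sequence[str], ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-sequence metric rows: length, FCR, kappa, SHD, SEG entropy, and
    the 20 composition frequencies (columns ``f_A`` ... ``f_Y``)."""
    if ids is None:
        ids = [f"seq_{i}" for i in range(len(seqs))]
    rows = []
    for sid, s in zip(ids, seqs):
        row: Dict[str, object] = {"id": sid, "length": len(s)}
        row["fcr"] = fcr(s)
        row["kappa"] = kappa(s) if len(s) >= 6 else float("nan")
        row["shd"] = shd(s) if len(s) >= 2 else float("nan")
        row["seg"] = seg_complexity(s)
        for aa, f in zip(CANONICAL_AA, composition(s)):
            row[f"f_{aa}"] = f
        rows.append(row)
    return pd.DataFrame(rows)
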