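"""pLDDT-based curation of intrinsically disordered regions.

AlphaFold's per-residue pLDDT confidence correlates strongly with local
disorder: confidently predicted residues (high pLDDT) are usually part of a
folded domain, while persistently low-confidence stretches are usually
intrinsically disordered. Curation turns a per-residue pLDDT trace into a
clean two-state segmentation and emits one record per disordered region
together with its N- and C-terminal flanking contexts.

The procedure:

1. smooth the raw trace with a centered moving average (window 15,
   shrinking at the termini);
2. classify each residue by threshold: smoothed score above 80 is FOLDED,
   below 70 is DISORDERED, anything in between (inclusive of both
   boundaries) is a GAP;
3. refine runs: FOLDED/DISORDERED runs shorter than 10 residues become
   gaps, adjacent gaps merge, a gap flanked by two disordered runs (or a
   terminal gap adjacent to a disordered run) becomes DISORDERED, every
   other gap becomes FOLDED;
4. emit one record per disordered segment, dropping IDRs shorter than 30
   residues, proteins longer than 512 residues, proteins that are entirely
   disordered, and proteins containing non-canonical residues.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from idiomkit.fim import CANONICAL_AA


class Label(str, Enum):
    FOLDED = "FOLDED"
    DISORDERED = "DISORDERED"
    GAP = "GAP"


@dataclass
class PlddtTrace:
    """A protein sequence with its per-residue pLDDT scores."""

    protein_id: str
    sequence: str
    plddt: np.ndarray

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if len(self.sequence) == 0:
            raise ValueError("empty sequence")
        if self.plddt.shape != (len(self.sequence),):
            raise ValueError(
                f"pLDDT length {self.plddt.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("pLDDT scores must lie in [0, 100]")


@dataclass
class SegmentationParams:
    """Thresholds and length cutoffs for the segmentation rules.

    window:
        moving-average width in residues (odd).
    fold_threshold / disorder_threshold:
        smoothed pLDDT above ``fold_threshold`` is folded, below
        ``disorder_threshold`` disordered; scores equal to either
        threshold, or strictly between them, are gaps.
    min_run:
        folded/disordered runs shorter than this are demoted to gaps.
    min_idr_len:
        disordered segments shorter than this are not emitted.
    max_protein_len:
        proteins longer than this are skipped entirely.
    """

    window: int = 15
    fold_threshold: float = 80.0
    disorder_threshold: float = 70.0
    min_run: int = 10
    min_idr_len: int = 30
    max_protein_len: int = 512

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if not self.disorder_threshold < self.fold_threshold:
            raise ValueError("disorder_threshold must be below fold_threshold")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class Segment:
    """Half-open residue interval [start, end) with a single label."""

    start: int
    end: int
    label: Label

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IdrRecord:
    """One curated IDR with its flanking contexts and 1-based coordinates."""

    protein_id: str
    n_context: str
    idr: str
    c_context: str
    idr_start: int  # 1-based inclusive
    idr_end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.idr_end - self.idr_start + 1 != len(self.idr):
            raise ValueError("coordinates inconsistent with IDR length")

    @property
    def full_sequence(self) -> str:
        return self.n_context + self.idr + self.c_context

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein_id": self.protein_id,
                "n_context": self.n_context,
                "idr": self.idr,
                "c_context": self.c_context,
                "idr_start": self.idr_start,
                "idr_end": self.idr_end,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "IdrRecord":
        d = json.loads(line)
        return cls(**{k: d[k] for k in (
            "protein_id", "n_context", "idr", "c_context", "idr_start", "idr_end")})


def smooth_plddt(trace: PlddtTrace | np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average with a shrinking window at the termini.

    Each output value is the mean of the raw scores within the centered
    window truncated to the trace; no values outside [0, 100] are ever
    invented by padding.
    """
    x = trace.plddt if isinstance(trace, PlddtTrace) else np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def classify_residues(
    smoothed: np.ndarray, params: SegmentationParams | None = None
) -> List[Label]:
    """Three-state threshold classification of smoothed scores.

    Scores exactly at a threshold fall in the GAP band: both stated rules
    (> fold_threshold folded, < disorder_threshold disordered) use strict
    inequalities, so equality satisfies neither.
    """
    p = params or SegmentationParams()
    s = np.asarray(smoothed, dtype=float)
    if np.any(s < 0) or np.any(s > 100):
        raise ValueError("scores must lie in [0, 100]")
    out: List[Label] = []
    for v in s:
        if v > p.fold_threshold:
            out.append(Label.FOLDED)
        elif v < p.disorder_threshold:
            out.append(Label.DISORDERED)
        else:
            out.append(Label.GAP)
    return out


def _runs(labels: Sequence[Label]) -> List[Segment]:
    segs: List[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append(Segment(start, i, labels[start]))
            start = i
    return segs


def _merge_adjacent(segs: List[Segment]) -> List[Segment]:
    out: List[Segment] = []
    for s in segs:
        if out and out[-1].label == s.label:
            out[-1] = Segment(out[-1].start, s.end, s.label)
        else:
            out.append(s)
    return out


def refine_segments(
    labels: Sequence[Label], params: SegmentationParams | None = None
) -> List[Segment]:
    """Collapse per-residue labels to a final two-state segmentation.

    Single pass, in order: short folded/disordered runs are demoted to
    gaps; adjacent gaps merge; a gap flanked by two disordered runs, or a
    terminal gap adjacent to a disordered run, becomes disordered; all
    other gaps become folded. A gap between one disordered and one folded
    neighbour (non-terminal) therefore becomes folded. The output tiles
    the protein with alternating FOLDED/DISORDERED segments and is a fixed
    point of the procedure.
    """
    p = params or SegmentationParams()
    if len(labels) == 0:
        raise ValueError("no labels")
    segs = _runs(list(labels))
    # demote short folded/disordered runs to gaps, then merge gap runs
    segs = [
        Segment(s.start, s.end, Label.GAP)
        if s.label is not Label.GAP and len(s) < p.min_run
        else s
        for s in segs
    ]
    segs = _merge_adjacent(segs)
    # relabel each gap run from its neighbours
    relabeled: List[Segment] = []
    for i, s in enumerate(segs):
        if s.label is not Label.GAP:
            relabeled.append(s)
            continue
        left = segs[i - 1].label if i > 0 else None
        right = segs[i + 1].label if i < len(segs) - 1 else None
        flanked_disordered = left is Label.DISORDERED and right is Label.DISORDERED
        terminal_disordered = (left is None and right is Label.DISORDERED) or (
            right is None and left is Label.DISORDERED
        )
        whole_protein_gap = left is None and right is None
        if flanked_disordered or terminal_disordered:
            new = Label.DISORDERED
        elif whole_protein_gap:
            new = Label.FOLDED
        else:
            new = Label.FOLDED
        relabeled.append(Segment(s.start, s.end, new))
    return _merge_adjacent(relabeled)


def segments_to_labels(segs: Sequence[Segment]) -> List[Label]:
    out: List[Label] = []
    for s in segs:
        out.extend([s.label] * len(s))
    return out


def extract_idr_records(
    trace: PlddtTrace,
    segments: Sequence[Segment],
    params: SegmentationParams | None = None,
) -> List[IdrRecord]:
    """Emit one record per disordered segment, applying the drop rules.

    Dropped: IDRs shorter than ``min_idr_len``; whole proteins longer than
    ``max_protein_len``, entirely disordered, or containing non-canonical
    residues. Flanking contexts are the full remainder of the protein on
    each side — other IDRs inside a flank are left as plain sequence.
    Serialized coordinates are 1-based inclusive (UniProt convention).
    """
    p = params or SegmentationParams()
    seq = trace.sequence
    total = sum(len(s) for s in segments)
    if total != len(seq):
        raise ValueError("segments do not tile the protein")
    if len(seq) > p.max_protein_len:
        return []
    if any(ch not in CANONICAL_AA for ch in seq):
        return []
    disordered = [s for s in segments if s.label is Label.DISORDERED]
    if len(disordered) == 1 and len(disordered[0]) == len(seq):
        return []  # entirely low-pLDDT protein
    records: List[IdrRecord] = []
    for s in disordered:
        if len(s) < p.min_idr_len:
            continue
        records.append(
            IdrRecord(
                protein_id=trace.protein_id,
                n_context=seq[: s.start],
                idr=seq[s.start : s.end],
                c_context=seq[s.end :],
                idr_start=s.start + 1,
                idr_end=s.end,
            )
        )
    return records


def curate_protein(
    trace: PlddtTrace, params: SegmentationParams | None = None
) -> List[IdrRecord]:
    """Full per-protein pipeline: smooth, classify, refine, extract."""
    p = params or SegmentationParams()
    smoothed = smooth_plddt(trace, p.window)
    labels = classify_residues(smoothed, p)
    segs = refine_segments(labels, p)
    return extract_idr_records(trace, segs, p)


# ---------------------------------------------------------------------------
# I/O helpers


def read_plddt_json(path: str | Path) -> np.ndarray:
    """AFDB-style confidence JSON: an object with a per-residue score array.

    Accepts ``{"plddt": [...]}`` as well as the AFDB field name
    ``confidenceScore``, or a bare JSON array.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        return np.asarray(obj, dtype=float)
    for key in ("plddt", "confidenceScore"):
        if key in obj:
            return np.asarray(obj[key], dtype=float)
    raise ValueError(f"no pLDDT array found in {path}")


def read_plddt_csv(path: str | Path) -> np.ndarray:
    """Two-column CSV (residue index, score); a header row is tolerated."""
    scores: List[Tuple[int, float]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                scores.append((int(row[0]), float(row[1])))
            except ValueError:
                continue  # header
    scores.sort()
    return np.asarray([s for _, s in scores], dtype=float)


def load_traces(fasta: str | Path, plddt_dir: str | Path) -> Iterable[PlddtTrace]:
    """Pair FASTA sequences with per-protein pLDDT files by protein id.

    For each FASTA record id, looks for ``<id>.json`` then ``<id>.csv``
    under ``plddt_dir``; records without a trace file are skipped.
    """
    from Bio import SeqIO

    plddt_dir = Path(plddt_dir)
    for rec in SeqIO.parse(str(fasta), "fasta"):
        jpath = plddt_dir / f"{rec.id}.json"
        cpath = plddt_dir / f"{rec.id}.csv"
        if jpath.exists():
            scores = read_plddt_json(jpath)
        elif cpath.exists():
            scores = read_plddt_csv(cpath)
        else:
            continue
        yield PlddtTrace(rec.id, str(rec.seq).upper(), scores)


def write_records(records: Iterable[IdrRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
            n += 1
    return n


def read_records(path: str | Path) -> List[IdrRecord]:
    with open(path) as fh:
        return [IdrRecord.from_json(line) for line in fh if line.strip()]
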