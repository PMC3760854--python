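"""Candidate-region extraction, fragment generation and motif scanning.

Short linear motifs (SLiMs) are 3-12 residue patterns that sit inside
intrinsically disordered regions.  The method works on a fixed-length window
(default 50 residues) around a motif: the window is centred on the motif
unless the motif sits near a terminus, in which case the terminal 50
residues are taken.  Within a window, overlapping k-mer fragments (default
tripeptides) are the docking ligands, and a mean-disorder rule decides
whether the window counts as disordered at all.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ValidationError

#: default candidate-region length (residues)
WINDOW_LENGTH = 50
#: default fragment (ligand) length; tripeptides balance docking cost and signal
FRAGMENT_LENGTH = 3
#: strict threshold on the mean disorder score of a window
DISORDER_THRESHOLD = 0.5

#: nuclear-receptor co-repressor (CoRNR box) motif, the worked proteome-scan
#: example shipped with the package
CORNR_BOX_PATTERN = r"L[^P]{2}[HI]I[^P]{2}[IAV][IL]"


@dataclass
class ProteinRegion:
    """A candidate window on a parent sequence, with per-residue labels.

    Coordinates are 1-based inclusive on the parent.  ``labels`` marks the
    binding (motif) residues within the region with 1.
    """

    parent_id: str
    parent_length: int
    start: int
    end: int
    seq: str
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.zeros(len(self.seq), dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.end - self.start + 1 != len(self.seq):
            raise ValidationError(
                f"region span {self.start}..{self.end} does not match "
                f"sequence length {len(self.seq)}"
            )
        if not (1 <= self.start <= self.end <= self.parent_length):
            raise ValidationError(
                f"region {self.start}..{self.end} outside parent of length "
                f"{self.parent_length}"
            )
        if len(self.labels) != len(self.seq):
            raise ValidationError("labels length does not match region length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifInstance:
    """One regular-expression match on a parent sequence (1-based span)."""

    parent_id: str
    start: int
    end: int
    matched: str


def extract_window(
    seq: str,
    motif_start: int,
    motif_end: int,
    window: int = WINDOW_LENGTH,
    parent_id: str = "",
) -> ProteinRegion:
    """Extract the candidate region around a motif span.

    If the parent is no longer than ``window`` the whole sequence is the
    region.  Otherwise the region is centred on the motif midpoint, except
    when that midpoint falls within the ``window/2`` residues closest to a
    terminus, in which case the terminal ``window`` residues are taken (so
    the region never runs off the sequence).  The motif midpoint is
    ``ceil((start + end) / 2)``; per-residue labels mark the motif residues
    that fall inside the region.
    """
    n = len(seq)
    if not (1 <= motif_start <= motif_end <= n):
        raise BoundsError(
            f"motif span {motif_start}..{motif_end} outside sequence of length {n}"
        )
    half = window // 2
    if n <= window:
        start, end = 1, n
    else:
        centre = math.ceil((motif_start + motif_end) / 2)
        if centre <= half:
            start, end = 1, window
        elif centre >= n - half + 1:
            start, end = n - window + 1, n
        else:
            start = centre - half + 1
            end = start + window - 1

    labels = np.zeros(end - start + 1, dtype=np.int8)
    lo = max(motif_start, start)
    hi = min(motif_end, end)
    if lo <= hi:
        labels[lo - start : hi - start + 1] = 1
    return ProteinRegion(
        parent_id=parent_id,
        parent_length=n,
        start=start,
        end=end,
        seq=seq[start - 1 : end],
        labels=labels,
    )


def generate_fragments(region: ProteinRegion | str, k: int = FRAGMENT_LENGTH) -> list[tuple[int, str]]:
    """Slide a length-``k`` window along the region.

    Returns ``len(region) - k + 1`` fragments as ``(offset, k-mer)`` pairs
    with 1-based offsets on the region.
    """
    seq = region.seq if isinstance(region, ProteinRegion) else region
    if not (1 <= k <= len(seq)):
        raise BoundsError(f"fragment length {k} out of range for region of length {len(seq)}")
    return [(i + 1, seq[i : i + k]) for i in range(len(seq) - k + 1)]


def scan_motif(seq: str, pattern: str, parent_id: str = "") -> list[MotifInstance]:
    """Find all (including overlapping) matches of a motif regex.

    Spans are 1-based inclusive, reported left to right.  Overlaps are kept
    because a protein can carry several instances of the same motif.
    """
    try:
        compiled = re.compile(f"(?=({pattern}))")
    except re.error as exc:
        raise ValidationError(f"invalid motif pattern {pattern!r}: {exc}") from None
    out = []
    for m in compiled.finditer(seq):
        matched = m.group(1)
        start = m.start() + 1
        out.append(
            MotifInstance(
                parent_id=parent_id,
                start=start,
                end=start + len(matched) - 1,
                matched=matched,
            )
        )
    return out


def disorder_filter(track, threshold: float = DISORDER_THRESHOLD) -> bool:
    """True iff the mean disorder score over the window strictly exceeds the threshold."""
    values = np.asarray(track, dtype=float)
    if values.size == 0:
        raise ValidationError("empty disorder track")
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise ValidationError("disorder scores must lie in [0, 1]")
    return float(values.mean()) > threshold
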