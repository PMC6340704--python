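"""Shared domain containers for barrel topology analysis."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ResidueRecord:
    """One residue's backbone: sequential 1-based index, one-letter code and
    N/CA/C/O coordinates (Angstrom)."""
    seq_index: int
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray


@dataclass
class BackboneGeometry:
    """Per-residue phi/psi in degrees; NaN where undefined (chain ends,
    degenerate atom quadruples)."""
    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


@dataclass
class StrandAnnotation:
    """Ordered, non-overlapping strand intervals (inclusive, 1-based) with
    optional per-strand membrane direction.

    direction +1: the strand runs periplasm -> extracellular (its N-terminal
    end sits on the periplasmic face); -1 the reverse.
    """
    strands: list[tuple[int, int]]
    directions: Optional[list[int]] = None
    protein_id: str = ""

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    def strand_of(self, pos: int) -> Optional[int]:
        """1-based strand index containing residue position pos, else None."""
        for i, (s, e) in enumerate(self.strands, start=1):
            if s <= pos <= e:
                return i
        return None

    def region_of(self, pos: int) -> tuple[str, int]:
        """Region of residue pos: ("strand", i) or ("loop", i) where loop i
        lies strictly between strand i and strand i+1 (loop 0 = N tail)."""
        k = 0
        for i, (s, e) in enumerate(self.strands, start=1):
            if pos < s:
                return ("loop", k)
            if s <= pos <= e:
                return ("strand", i)
            k = i
        return ("loop", k)

    def validate(self) -> None:
        prev_end = 0
        for s, e in self.strands:
            if s > e:
                raise ValueError(f"inverted strand interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("strand intervals overlap or are unordered")
            prev_end = e
        if self.directions is not None and len(self.directions) != len(self.strands):
            raise ValueError("directions length must match strand count")


@dataclass
class AlignmentRecord:
    """One pairwise (local, gapped, colinear) alignment between two proteins.

    aligned_pairs holds 1-based (query_pos, target_pos) tuples, strictly
    increasing in both coordinates.
    """
    query_id: str
    target_id: str
    evalue: float
    probability: Optional[float] = None
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def is_self(self) -> bool:
        return self.query_id == self.target_id

    @property
    def n_aligned(self) -> int:
        if self.aligned_pairs:
            return len(self.aligned_pairs)
        return int(self.meta.get("n_aligned", 0))

    def validate(self) -> None:
        if not (self.evalue > 0):
            raise ValueError("evalue must be positive")
        if self.probability is not None and not (0 <= self.probability <= 100):
            raise ValueError("probability must be a percent in [0, 100]")
        prev = (0, 0)
        for q, t in self.aligned_pairs:
            if q <= prev[0] or t <= prev[1]:
                raise ValueError("aligned_pairs must be strictly increasing in both coordinates")
            prev = (q, t)


@dataclass
class CrossMatch:
    """A region-level correspondence that is not part of the colinear
    strand-to-strand chain (loop<->strand matches, leftover strand pairs)."""
    q_kind: str  # "strand" | "loop"
    q_index: int
    t_kind: str
    t_index: int
    support: int


@dataclass
class StrandCorrespondence:
    """Strand-level projection of one alignment.

    strand_pairs: (q_strand, t_strand, support) on the selected colinear
    chain; cross_matches: everything else that clears the support threshold.
    """
    query_id: str
    target_id: str
    strand_pairs: list[tuple[int, int, int]]
    cross_matches: list[CrossMatch]
    q_n: int
    t_n: int
    is_self: bool = False
    theta: dict = field(default_factory=dict)


# Topological categories for cross-protein alignments.
CTERM_ANCHORED = "CTERM_ANCHORED"
NTERM_ANCHORED = "NTERM_ANCHORED"
INTERNAL_OFFSET = "INTERNAL_OFFSET"
LOOP_TO_HAIRPIN = "LOOP_TO_HAIRPIN"
LOOP_TO_HAIRPIN_ALT = "LOOP_TO_HAIRPIN_ALT"
LARGE_REARRANGEMENT = "LARGE_REARRANGEMENT"
OTHER = "OTHER"
CATEGORIES = (CTERM_ANCHORED, NTERM_ANCHORED, INTERNAL_OFFSET, LOOP_TO_HAIRPIN,
              LOOP_TO_HAIRPIN_ALT, LARGE_REARRANGEMENT, OTHER)

# Repeat classes for self-alignments.
HAIRPIN_SHIFT = "HAIRPIN_SHIFT"
DOUBLE_HAIRPIN_SHIFT = "DOUBLE_HAIRPIN_SHIFT"
REPEAT_OTHER = "OTHER"
REPEAT_NONE = "NONE"


@dataclass
class ClassifiedAlignment:
    """Category label for one alignment plus provenance flags."""
    query_id: str
    target_id: str
    category: str = OTHER
    repeat_class: str = REPEAT_NONE
    includes_last_strands: bool = False
    covers_all_query_strands: bool = False
    has_redirection: bool = False
    has_alternate_alignment: bool = False
    insufficient: bool = False
    ambiguous_anchor: bool = False
    evalue: Optional[float] = None
    q_n: int = 0
    t_n: int = 0
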