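"""Backend-independent logo geometry.

Turns motifs (single or pairs) into per-position symbol stacks: each stack
is an ordered list of segments ``(symbol, signed height, baseline offset)``
in ordinate units (bits).  Rendering backends only scale these numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import AlphabetError, LengthMismatchError, MotifError
from .measures import (
    DEFAULT_MEASURES,
    MeasurePair,
    classic_symbol_heights,
    difference_column,
)
from .model import Alphabet, ProbabilityMotif

#: heights below this are treated as zero and dropped from stacks
ZERO_HEIGHT = 1e-12


class Segment(NamedTuple):
    symbol: str
    height: float   # signed: negative segments hang below the axis
    baseline: float  # offset of the segment's axis-side edge


@dataclass(frozen=True)
class LogoColumns:
    """Renderable stacks for one logo.

    ``kind`` is ``"sequence"`` (all heights >= 0, ordinate from 0) or
    ``"difference"`` (signed heights, ordinate symmetric about 0).
    """

    kind: str
    columns: tuple  # tuple of tuples of Segment
    ordinate_max: float
    ordinate_min: float
    alphabet: Alphabet
    label: str = ""

    @property
    def length(self) -> int:
        return len(self.columns)

    def column_extents(self, i: int):
        """(bottom, top) extent of column ``i`` (0-based)."""
        top = sum(s.height for s in self.columns[i] if s.height > 0)
        bottom = sum(s.height for s in self.columns[i] if s.height < 0)
        return bottom, top

    @property
    def max_extent(self) -> float:
        """Largest absolute stack extent over all columns (0 for empty logos)."""
        if not self.columns:
            return 0.0
        return max(
            max(abs(b), abs(t)) for b, t in (self.column_extents(i) for i in range(self.length))
        )


def _stack_side(heights, alphabet: Alphabet, sign: int):
    """Stack one side of the axis: ascending |height| from the baseline out.

    The most-changed symbol therefore sits outermost (top of the upward
    stack, bottom of the downward one); ties break by alphabet order.
    """
    entries = [
        (abs(h), alphabet.index(sym), sym, h)
        for sym, h in heights
        if abs(h) > ZERO_HEIGHT and (h > 0) == (sign > 0)
    ]
    entries.sort(key=lambda e: (e[0], e[1]))
    segments = []
    offset = 0.0
    for _, _, sym, h in entries:
        segments.append(Segment(symbol=sym, height=h, baseline=offset))
        offset += h
    return segments


def build_sequence_logo(motif: ProbabilityMotif, ordinate_max: float | None = None) -> LogoColumns:
    """Classic sequence-logo geometry: letter heights p * information content.

    Within a stack, letters ascend from the baseline so the most frequent
    symbol is adjacent to the top.  The default ordinate bound is
    ``log2 |alphabet|``, the maximum attainable information content.
    """
    cols = []
    for ell in range(motif.length):
        heights = classic_symbol_heights(motif.probs[ell])
        cols.append(tuple(_stack_side(zip(motif.alphabet.symbols, heights), motif.alphabet, +1)))
    if ordinate_max is None:
        ordinate_max = float(np.log2(motif.alphabet.size))
    if ordinate_max <= 0:
        raise MotifError("ordinate_max must be positive")
    return LogoColumns(
        kind="sequence",
        columns=tuple(cols),
        ordinate_max=float(ordinate_max),
        ordinate_min=0.0,
        alphabet=motif.alphabet,
        label=motif.label,
    )


def build_difference_logo(
    p: ProbabilityMotif,
    q: ProbabilityMotif,
    measures: MeasurePair = DEFAULT_MEASURES,
    ordinate_max: float | None = None,
) -> LogoColumns:
    """Difference-logo geometry for a motif pair.

    Symbols more abundant in the first motif (positive signed height) stack
    upward, those more abundant in the second stack downward; each side
    ascends in magnitude away from the axis.  The ordinate is symmetric
    about zero and, by default, data-driven (the largest stack extent, or 1
    bit for identical motifs).
    """
    if p.alphabet.symbols != q.alphabet.symbols:
        raise AlphabetError("motifs are over different alphabets")
    if p.length != q.length:
        raise LengthMismatchError(
            f"motif lengths differ ({p.length} vs {q.length}); pad first to compare"
        )
    cols = []
    for ell in range(p.length):
        column = difference_column(p.probs[ell], q.probs[ell], measures, position=ell + 1)
        pairs = list(zip(p.alphabet.symbols, column.symbol_heights))
        up = _stack_side(pairs, p.alphabet, +1)
        down = _stack_side(pairs, p.alphabet, -1)
        cols.append(tuple(up + down))
    geometry = LogoColumns(
        kind="difference",
        columns=tuple(cols),
        ordinate_max=1.0,  # placeholder, replaced below
        ordinate_min=-1.0,
        alphabet=p.alphabet,
        label=f"{p.label} vs {q.label}",
    )
    if ordinate_max is None:
        ordinate_max = geometry.max_extent or 1.0
    if ordinate_max <= 0:
        raise MotifError("ordinate_max must be positive")
    return LogoColumns(
        kind="difference",
        columns=geometry.columns,
        ordinate_max=float(ordinate_max),
        ordinate_min=-float(ordinate_max),
        alphabet=p.alphabet,
        label=geometry.label,
    )


def common_ordinate(logos) -> float:
    """Shared ordinate bound: the maximum absolute stack extent over logos.

    Used so every cell of a comparison grid is drawn on the same scale.
    """
    logos = list(logos)
    if not logos:
        raise MotifError("common_ordinate needs at least one logo")
    return max(logo.max_extent for logo in logos)
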