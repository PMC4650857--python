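"""Scalar measures behind sequence and difference logos.

A classic sequence logo draws, at each position, a symbol stack of height

    H_l = log2|A| - sum_a p_{l,a} log2 p_{l,a}        (information content)

with each symbol occupying p_{l,a} * H_l of the stack.  A difference logo
redefines both quantities for a *pair* of per-position distributions p_l,
q_l: the stack height becomes the Jensen-Shannon divergence

    H_l = 1/2 sum_a p_{l,a} log2(p_{l,a}/m_{l,a})
        + 1/2 sum_a q_{l,a} log2(q_{l,a}/m_{l,a}),    m = (p+q)/2

bounded by 1 bit, and the signed symbol heights become H_{l,a} = r_{l,a} H_l
with the normalized probability difference

    r_{l,a} = (p_{l,a} - q_{l,a}) / sum_a' |p_{l,a'} - q_{l,a'}|

(zero when p_l = q_l).  Symbols more abundant in the first motif point up,
symbols more abundant in the second point down, and both sides balance at
every position.  Summing stack heights over positions gives the scalar
dissimilarity D used for clustering and grid coloring.

Both the stack height and the symbol weight are pluggable via
:class:`MeasurePair`; alternatives live in a registry
(:func:`alternative_measures`).  All logarithms are base 2; the unit is bits
throughout, with the 0*log2(0) := 0 continuity convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError, LengthMismatchError, MeasureLookupError, MotifError
from .model import ProbabilityMotif, pad_motifs

#: componentwise tolerance for the "p_l equals q_l" test of the weight formula
EQUALITY_ATOL = 1e-12


def _as_distribution(v, name: str = "distribution") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise MotifError(f"{name} must be a 1-D vector of length >= 2")
    if np.any(v < -EQUALITY_ATOL) or abs(v.sum() - 1.0) > 1e-9:
        raise MotifError(f"{name} is not a probability distribution (sum {v.sum()})")
    return np.clip(v, 0.0, 1.0)


def _check_pair(p, q):
    p = _as_distribution(p, "p")
    q = _as_distribution(q, "q")
    if p.shape != q.shape:
        raise AlphabetError(
            f"distributions over different alphabets: sizes {p.size} vs {q.size}"
        )
    return p, q


def information_content(p, alphabet_size: int | None = None) -> float:
    """Information content of one position, in bits: log2|A| minus entropy."""
    p = _as_distribution(p, "p")
    n = alphabet_size if alphabet_size is not None else p.size
    if n != p.size:
        raise AlphabetError(f"alphabet_size {n} does not match vector length {p.size}")
    pos = p[p > 0]
    ic = np.log2(n) + float(np.sum(pos * np.log2(pos)))
    return float(min(max(ic, 0.0), np.log2(n)))


def classic_symbol_heights(p, alphabet_size: int | None = None) -> np.ndarray:
    """Classic sequence-logo letter heights: p_{l,a} * H_l (all non-negative)."""
    p = _as_distribution(p, "p")
    return p * information_content(p, alphabet_size)


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence of two positions, in bits (in [0, 1]).

    Symmetric, zero iff p = q, maximal (1 bit) only for disjoint supports.
    Terms with zero probability contribute 0.
    """
    p, q = _check_pair(p, q)
    m = 0.5 * (p + q)

    def half(x):
        mask = x > 0
        return float(np.sum(x[mask] * np.log2(x[mask] / m[mask])))

    return max(0.5 * half(p) + 0.5 * half(q), 0.0)


def normalized_prob_difference(p, q) -> np.ndarray:
    """Probability difference p - q normalized by its absolute sum.

    Returns the all-zero vector when p = q (within ``EQUALITY_ATOL``);
    otherwise sums to 0 with absolute sum 1.  Antisymmetric in (p, q).
    """
    p, q = _check_pair(p, q)
    diff = p - q
    if np.max(np.abs(diff)) <= EQUALITY_ATOL:
        return np.zeros_like(diff)
    return diff / np.sum(np.abs(diff))


def sum_abs_prob_difference(p, q) -> float:
    """Alternative stack height: total variation-style sum of |p - q| (in [0, 2])."""
    p, q = _check_pair(p, q)
    return float(np.sum(np.abs(p - q)))


def information_content_difference(p, q) -> float:
    """Alternative stack height: absolute difference of information contents."""
    p, q = _check_pair(p, q)
    return abs(information_content(p) - information_content(q))


def raw_prob_difference(p, q) -> np.ndarray:
    """Alternative symbol weight: the unnormalized difference p - q.

    Sums to 0; its absolute sum can reach 2 (it is not normalized).
    """
    p, q = _check_pair(p, q)
    return p - q


@dataclass(frozen=True)
class MeasurePair:
    """A pluggable (stack height, symbol weight) combination.

    ``stack_height(p, q)`` must be non-negative and vanish on p = q;
    ``symbol_weight(p, q)`` must sum to zero.
    """

    stack_height: callable
    symbol_weight: callable
    names: tuple = ("jensen_shannon", "normalized_prob_diff")


STACK_HEIGHTS = {
    "jensen_shannon": js_divergence,
    "sum_abs_prob_diff": sum_abs_prob_difference,
    "info_content_diff": information_content_difference,
}

SYMBOL_WEIGHTS = {
    "normalized_prob_diff": normalized_prob_difference,
    "raw_prob_diff": raw_prob_difference,
}


def alternative_measures() -> dict:
    """Registry of named stack-height and symbol-weight implementations."""
    return {
        "stack_heights": dict(STACK_HEIGHTS),
        "symbol_weights": dict(SYMBOL_WEIGHTS),
    }


def get_measures(
    stack_height: str = "jensen_shannon",
    symbol_weight: str = "normalized_prob_diff",
) -> MeasurePair:
    """Look up a :class:`MeasurePair` by component names."""
    try:
        h = STACK_HEIGHTS[stack_height]
    except KeyError:
        raise MeasureLookupError(
            f"unknown stack height {stack_height!r}; "
            f"available: {sorted(STACK_HEIGHTS)}"
        ) from None
    try:
        r = SYMBOL_WEIGHTS[symbol_weight]
    except KeyError:
        raise MeasureLookupError(
            f"unknown symbol weight {symbol_weight!r}; "
            f"available: {sorted(SYMBOL_WEIGHTS)}"
        ) from None
    return MeasurePair(stack_height=h, symbol_weight=r, names=(stack_height, symbol_weight))


DEFAULT_MEASURES = get_measures()


@dataclass(frozen=True)
class DifferenceColumn:
    """One position of a difference logo.

    ``symbol_heights`` are signed (positive: more abundant in the first
    motif); they sum to zero, and with the default normalized weights the
    absolute heights sum to ``stack_height``.
    """

    position: int  # 1-based
    stack_height: float
    symbol_heights: np.ndarray


def difference_column(p, q, measures: MeasurePair = DEFAULT_MEASURES, position: int = 1) -> DifferenceColumn:
    """Stack height and signed symbol heights for one position pair."""
    p, q = _check_pair(p, q)
    h = float(measures.stack_height(p, q))
    r = np.asarray(measures.symbol_weight(p, q), dtype=float)
    return DifferenceColumn(position=position, stack_height=h, symbol_heights=r * h)


def motif_dissimilarity(
    p: ProbabilityMotif,
    q: ProbabilityMotif,
    measures: MeasurePair = DEFAULT_MEASURES,
    pad: bool = False,
) -> float:
    """Scalar dissimilarity D: the sum of per-position stack heights.

    Non-negative, symmetric, zero iff the motifs are identical, and additive
    over position blocks.  Not a metric (no triangle inequality — the
    Jensen-Shannon divergence without a square root is not one), which is
    fine for its role: clustering and grid coloring.
    """
    if p.alphabet.symbols != q.alphabet.symbols:
        raise AlphabetError("motifs are over different alphabets")
    if p.length != q.length:
        if not pad:
            raise LengthMismatchError(
                f"motif lengths differ ({p.length} vs {q.length}); "
                "enable padding to compare anyway"
            )
        p, q = pad_motifs(p, q)
    return float(
        sum(measures.stack_height(p.probs[i], q.probs[i]) for i in range(p.length))
    )
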