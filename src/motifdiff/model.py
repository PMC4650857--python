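"""Core motif data types.

A sequence motif summarizes a set of aligned, equal-length biopolymer
subsequences (e.g. transcription-factor binding sites) as a matrix over an
alphabet: either raw per-position symbol counts (:class:`CountMotif`) or
per-position symbol probabilities (:class:`ProbabilityMotif`, rows summing
to one).  Positions are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlphabetError,
    DegenerateColumnError,
    LengthMismatchError,
    MotifError,
    NormalizationError,
)

#: maximum deviation of a probability row from sum 1 after construction
ROW_SUM_TOL = 1e-9

_DEFAULT_COLOR = "#333333"

_DNA_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
_RNA_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "U": "#D62839"}

# WebLogo-style chemistry coloring for amino acids
_AA_CLASS_COLORS = {
    "polar": "#109648",        # G S T Y C
    "neutral": "#8E44AD",      # Q N
    "basic": "#255C99",        # K R H
    "acidic": "#D62839",       # D E
    "hydrophobic": "#2B2B2B",  # A V L I P W F M
}
_AA_CLASSES = {
    "G": "polar", "S": "polar", "T": "polar", "Y": "polar", "C": "polar",
    "Q": "neutral", "N": "neutral",
    "K": "basic", "R": "basic", "H": "basic",
    "D": "acidic", "E": "acidic",
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "P": "hydrophobic", "W": "hydrophobic",
    "F": "hydrophobic", "M": "hydrophobic",
}


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of single-character symbols with display colors.

    Symbols are case-normalized to upper case and must be unique; an
    alphabet has at least two symbols.
    """

    symbols: tuple
    name: str = "custom"
    color_map: dict = field(default_factory=dict)

    def __post_init__(self):
        syms = tuple(str(s).upper() for s in self.symbols)
        if any(len(s) != 1 for s in syms):
            raise AlphabetError("alphabet symbols must be single characters")
        if len(set(syms)) != len(syms):
            raise AlphabetError(f"duplicate symbols in alphabet: {syms}")
        if len(syms) < 2:
            raise AlphabetError("an alphabet needs at least 2 symbols")
        object.__setattr__(self, "symbols", syms)
        colors = {str(k).upper(): v for k, v in self.color_map.items()}
        object.__setattr__(self, "color_map", colors)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol.upper())
        except ValueError:
            raise AlphabetError(
                f"symbol {symbol!r} not in alphabet {self.name!r}"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def color(self, symbol: str) -> str:
        return self.color_map.get(symbol.upper(), _DEFAULT_COLOR)

    def __len__(self) -> int:
        return len(self.symbols)


DNA = Alphabet(("A", "C", "G", "T"), name="DNA", color_map=_DNA_COLORS)
RNA = Alphabet(("A", "C", "G", "U"), name="RNA", color_map=_RNA_COLORS)
PROTEIN = Alphabet(
    tuple("ACDEFGHIKLMNPQRSTVWY"),
    name="protein",
    color_map={aa: _AA_CLASS_COLORS[cls] for aa, cls in _AA_CLASSES.items()},
)

#: characters ignored by default when tallying aligned sequences
GAP_LIKE = {"-", ".", "N", "X"}


def alphabet_by_name(name: str) -> Alphabet:
    """Resolve ``dna`` / ``rna`` / ``protein`` / ``custom:<symbols>``."""
    key = name.strip()
    low = key.lower()
    if low == "dna":
        return DNA
    if low == "rna":
        return RNA
    if low == "protein":
        return PROTEIN
    if low.startswith("custom:"):
        return Alphabet(tuple(key.split(":", 1)[1]), name="custom")
    raise AlphabetError(f"unknown alphabet {name!r} (dna|rna|protein|custom:<symbols>)")


@dataclass(frozen=True)
class CountMotif:
    """Per-position symbol counts: an L x |alphabet| integer matrix."""

    alphabet: Alphabet
    counts: np.ndarray
    label: str = "motif"

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1:
            raise MotifError("counts must be a 2-D matrix with at least one row")
        if counts.shape[1] != self.alphabet.size:
            raise AlphabetError(
                f"counts have {counts.shape[1]} columns but alphabet "
                f"{self.alphabet.name!r} has {self.alphabet.size} symbols"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise MotifError("counts must be finite and non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise MotifError("counts must be integers")
        counts = np.round(counts).astype(np.int64)
        zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
        if zero_rows.size:
            raise DegenerateColumnError(
                f"all-zero count column(s) at position(s) {(zero_rows + 1).tolist()}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class ProbabilityMotif:
    """Per-position symbol probabilities: an L x |alphabet| row-stochastic matrix."""

    alphabet: Alphabet
    probs: np.ndarray
    label: str = "motif"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] < 1:
            raise MotifError("probs must be a 2-D matrix with at least one row")
        if probs.shape[1] != self.alphabet.size:
            raise AlphabetError(
                f"probs have {probs.shape[1]} columns but alphabet "
                f"{self.alphabet.name!r} has {self.alphabet.size} symbols"
            )
        if not np.all(np.isfinite(probs)):
            raise MotifError("probabilities must be finite")
        if np.any(probs < 0) or np.any(probs > 1 + ROW_SUM_TOL):
            raise MotifError("probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise NormalizationError(
                f"row(s) {(bad + 1).tolist()} do not sum to 1 "
                f"(sums {sums[bad].tolist()})"
            )
        probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def position(self, ell: int) -> np.ndarray:
        """Distribution at 1-based position ``ell``."""
        if not 1 <= ell <= self.length:
            raise MotifError(f"position {ell} outside [1, {self.length}]")
        return self.probs[ell - 1]


def sequences_to_counts(
    sequences,
    alphabet: Alphabet,
    unknown_policy: str = "skip",
    label: str = "motif",
) -> CountMotif:
    """Tally aligned equal-length sequences into a :class:`CountMotif`.

    With ``unknown_policy="skip"`` (the default for FASTA input), symbols
    outside the alphabet — gaps and ambiguity codes such as ``-``, ``.``,
    ``N``, ``X`` — contribute to no cell; a position where every sequence
    was skipped is a degenerate column and an error.  With
    ``unknown_policy="error"`` any out-of-alphabet symbol raises.
    """
    if unknown_policy not in ("skip", "error"):
        raise MotifError(f"unknown_policy must be 'skip' or 'error', got {unknown_policy!r}")
    seqs = [str(s).upper() for s in sequences]
    if not seqs:
        raise MotifError("need at least one sequence")
    length = len(seqs[0])
    if length < 1:
        raise LengthMismatchError("sequences must have length >= 1")
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise LengthMismatchError(
                f"sequence {i + 1} has length {len(s)}, expected {length}"
            )
    counts = np.zeros((length, alphabet.size), dtype=np.int64)
    lookup = {sym: j for j, sym in enumerate(alphabet.symbols)}
    for s in seqs:
        for ell, ch in enumerate(s):
            j = lookup.get(ch)
            if j is None:
                if unknown_policy == "error":
                    raise AlphabetError(
                        f"symbol {ch!r} at position {ell + 1} not in alphabet "
                        f"{alphabet.name!r}"
                    )
                continue
            counts[ell, j] += 1
    return CountMotif(alphabet=alphabet, counts=counts, label=label)


def counts_to_probabilities(motif: CountMotif, pseudocount: float = 0.0) -> ProbabilityMotif:
    """Convert counts to probabilities with an additive per-symbol pseudocount.

    ``p[l, a] = (counts[l, a] + pseudocount) / (sum_a' counts[l, a'] + |A| * pseudocount)``
    """
    if pseudocount < 0:
        raise MotifError("pseudocount must be non-negative")
    counts = motif.counts.astype(float) + pseudocount
    sums = counts.sum(axis=1)
    # CountMotif construction already rejects all-zero columns, but guard
    # anyway for the pseudocount-0 contract
    if np.any(sums <= 0):
        raise DegenerateColumnError("all-zero column with pseudocount 0")
    probs = counts / sums[:, None]
    return ProbabilityMotif(alphabet=motif.alphabet, probs=probs, label=motif.label)


def validate_probability_motif(
    matrix,
    alphabet: Alphabet,
    tolerance: float = 1e-6,
    label: str = "motif",
) -> ProbabilityMotif:
    """Build a :class:`ProbabilityMotif` from near-stochastic rows.

    Rows whose sum deviates from 1 by at most ``tolerance`` are renormalized
    to sum exactly 1; larger deviations or negative entries raise.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise MotifError("expected a 2-D matrix")
    if np.any(matrix < 0):
        raise MotifError("negative entry in probability matrix")
    sums = matrix.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tolerance)
    if bad.size:
        raise NormalizationError(
            f"row(s) {(bad + 1).tolist()} sum to {sums[bad].tolist()}, "
            f"outside 1 +/- {tolerance}"
        )
    return ProbabilityMotif(alphabet=alphabet, probs=matrix / sums[:, None], label=label)


def random_motif(
    alphabet: Alphabet,
    length: int,
    concentration: float = 1.0,
    seed: int = 0,
    label: str | None = None,
) -> ProbabilityMotif:
    """Draw a synthetic motif: each position i.i.d. symmetric Dirichlet.

    Small ``concentration`` (< 1) gives sharply conserved positions, large
    values approach the uniform distribution.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise MotifError("length must be >= 1")
    if concentration <= 0:
        raise MotifError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * alphabet.size, size=length)
    return ProbabilityMotif(
        alphabet=alphabet,
        probs=probs,
        label=label if label is not None else f"random_{seed}",
    )


def pad_motifs(p: ProbabilityMotif, q: ProbabilityMotif):
    """Extend the shorter motif symmetrically with uniform columns.

    Uniform columns are the least-assumptive padding: against another
    near-uniform column they contribute near-zero divergence.  The extra
    column goes to the right when the length difference is odd.
    """
    if p.alphabet.symbols != q.alphabet.symbols:
        raise AlphabetError("cannot pad motifs over different alphabets")
    if p.length == q.length:
        return p, q

    def _pad(motif: ProbabilityMotif, target: int) -> ProbabilityMotif:
        extra = target - motif.length
        left = extra // 2
        right = extra - left
        uniform = np.full((1, motif.alphabet.size), 1.0 / motif.alphabet.size)
        probs = np.vstack(
            [np.repeat(uniform, left, axis=0), motif.probs, np.repeat(uniform, right, axis=0)]
        )
        return ProbabilityMotif(alphabet=motif.alphabet, probs=probs, label=motif.label)

    target = max(p.length, q.length)
    return (_pad(p, target) if p.length < target else p,
            _pad(q, target) if q.length < target else q)
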