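# Methods

## Model and assumptions

A motif is an independent-positions model: an `L x |A|` row-stochastic
matrix of per-position symbol probabilities, typically estimated as
relative frequencies of a set of aligned, equal-length sequences.
Dependencies between positions are deliberately ignored — every quantity in
the package is a sum or maximum over per-position terms.  Comparisons
therefore assume the two motifs are already aligned to a common coordinate
system; the package performs no offset search or reverse-complement
matching (out of scope by design).

## Measures

All logarithms are base 2 and all heights are in bits.  The default
per-position stack height is the Jensen-Shannon divergence

    H = 1/2 sum_a p_a log2(p_a/m_a) + 1/2 sum_a q_a log2(q_a/m_a),
    m_a = (p_a + q_a)/2,

with the continuity convention `0*log2(0) = 0` (and `p*log2(p/m) = 0` when
`p = 0`; `m > 0` wherever either distribution is positive).  This
convention is what makes the fully-conserved-vs-different-base column come
out at exactly 1 bit.  The divergence is symmetric and bounded in [0, 1]
bits, with the maximum attained only for disjoint supports.  Tiny negative
results from floating-point cancellation are clamped to 0.

The default symbol weight is the normalized probability difference
`r_a = (p_a - q_a) / sum_a' |p_a' - q_a'|`, defined as the zero vector when
the distributions are equal.  "Equal" is tested as a maximum componentwise
difference of at most 1e-12 — inputs arrive through floating-point
normalization, so exact equality would be fragile.  With this weight the
signed symbol heights `r_a * H` sum to zero, their absolute values sum to
`H`, and each side of the axis carries exactly `H/2`.

The scalar dissimilarity `D` is the sum of stack heights over positions.
It is non-negative, symmetric, zero exactly on identical motifs, and
additive over position blocks.  It is *not* a metric: the Jensen-Shannon
divergence without a square root violates the triangle inequality, which is
acceptable because `D` only drives clustering and coloring, never
embedding.

Both components are pluggable (`MeasurePair`).  The registry ships
`sum_abs_prob_diff` (total-variation-style, range [0, 2]) and
`info_content_diff` as alternative stack heights and `raw_prob_diff`
(`p - q`, unnormalized) as an alternative symbol weight.  Note that
`raw_prob_diff` sums to zero but its absolute sum can reach 2; the
unit-absolute-sum property holds only for the normalized default, and
invariant checks are scoped accordingly.

## Logo geometry

Geometry is computed independently of any drawing backend: each position
becomes a stack of `(symbol, signed height, baseline offset)` segments.
Within a side of the axis, segments are ordered by ascending magnitude from
the baseline outward, so the most frequent (sequence logo) or most changed
(difference logo) symbol is outermost and most salient; ties break by
alphabet order.  Zero-height segments (|h| <= 1e-12) are dropped rather
than emitted as degenerate glyphs.  Sequence logos use a fixed ordinate of
`log2 |A|` (2 bits for DNA, ~4.32 for the 20 amino acids) for
comparability; difference logos use a data-driven symmetric ordinate, and
grids replace it with the common bound over all cells so every cell shares
one scale.  An all-empty difference logo (identical motifs) falls back to a
1-bit ordinate so axes remain drawable.

## Multi-motif comparison

Pairwise `D` values fill a symmetric matrix (validated symmetric to 1e-12
with a zero diagonal).  Hierarchical clustering delegates to
`scipy.cluster.hierarchy.linkage`; the default linkage is complete, with
average and single selectable — the choice affects only the tree and the
ordering, never the `D` values.

Leaf ordering is re-implemented as the exact dynamic program over subtree
flips: for every node and every (leftmost, rightmost) leaf pair of its
subtree, the cheapest internal arrangement is tabulated, and the root
minimum is reconstructed.  Among all `2^(N-1)` flip-consistent orders this
minimizes the sum of `D` over adjacent leaves; ties break
lexicographically by label so figures are reproducible and invariant to
input order (up to the always-equivalent full reversal).  The test suite
verifies exact equality with exhaustive flip enumeration for N up to 8.
During development the corresponding scipy routine
(`optimal_leaf_ordering`) was measured to return a costlier ordering on a
substantial fraction of random instances, so tests use it only as a
never-worse baseline, with exhaustive enumeration as the authority.

Cell background colors interpolate linearly in RGB between the palette
endpoints (`#00B000` green to `#D00000` red by default), mapping the
minimal off-diagonal `D` to green and the maximal to red.  When all
off-diagonal values coincide (e.g. identical motifs) the degenerate range
maps everything to the "similar" endpoint, avoiding a 0/0.

## Input handling

- Counts are converted to probabilities with an additive pseudocount
  (default 0 in the library; the CLI applies Laplace's +1 when reading
  count matrices, overridable via `--pseudocount`).  A pseudocount of 0
  requires strictly positive column sums.
- Aligned sequences are upper-cased; symbols outside the alphabet (gaps
  `-`, `.`, ambiguity codes `N`, `X`, ...) are skipped by default, and a
  position where *every* sequence was skipped is an error rather than a
  silent hole.  An `error` policy rejects any unknown symbol.  RNA `U` is
  mapped to `T` only on explicit request (`--rna-as-dna`); silent
  remapping hides data errors.
- Tabular matrices are never transposed by guesswork: a square `|A| x |A|`
  matrix without an explicit orientation is an error.
- Probability rows within `tolerance` of sum 1 (1e-4 for file input, since
  published matrices are often printed rounded) are renormalized; larger
  deviations are errors.
- Motifs of unequal length are an error by default; opt-in padding extends
  the shorter motif symmetrically with uniform columns, the
  least-assumptive filler (uniform-vs-near-uniform columns contribute
  near-zero divergence).
- Newick export uses the convention in which a node merged at height `h`
  sits at ultrametric depth `h/2`, so a two-leaf tree reads
  `(A:h/2,B:h/2);`.
- The distance-matrix TSV is written with 10 significant digits so that a
  write/read round trip stays within 1e-6 absolutely for `D` values of
  typical magnitude (tens of bits at most).

## Rendering

Letters are polygon glyphs from a built-in 5x7 bitmap outline font, not
font-rendered text: output is identical across systems, SVG output is
byte-stable (no timestamps), and tests can parse geometry back out of the
file instead of comparing pixels.  Each stack segment becomes one SVG
`<path>` of class `glyph` (its subpaths are the letter's filled cells, so
counters — the holes of A, B, O — come out automatically).  Grid SVGs mark
cell backgrounds with class `cellbg`, the dendrogram with `tree`, and
header logos with `headerlogo`, which is what the round-trip tests key on.
PNG and PDF output render the same rectangles through matplotlib (Agg).
Default DNA colors are A green, C blue, G orange, T red; amino acids are
colored by chemistry class.

## Synthetic data

The generator draws each position of a motif i.i.d. from a symmetric
Dirichlet.  Concentration 0.2 emulates sharply conserved binding-site
positions, 1.0 a flat prior, 5.0 weakly informative positions; default
test motifs use length 5-8 and concentrations in this range, which spans
the conservation profiles seen in real transcription-factor motifs.  What
the generator does *not* emulate: positional dependence, alignment error,
motif flanks with compositional bias, and finite-sample noise in count
estimates (the fixture writer adds the latter by multinomial sampling at
depth 200).  Passing tests therefore demonstrate correctness of the
measures, ordering and rendering pipeline on clean independent-position
motifs — not robustness to misaligned or dependent real data, which the
model class itself does not represent.

The fixture writer also emits four canonical length-1 toy pairs.  Three
have closed-form divergences (1, 1 and 0.5 bits).  The fourth, "two
differentially abundant bases" at 0.25 bit, does not pin down a unique
distribution pair; the writer uses the symmetric pair `(x, 1-x)` vs
`(1-x, x)` whose divergence `1 - H2(x)` is solved numerically for 0.25 —
an approximation by construction, documented as such.

## Numerical choices

- Probability rows must sum to 1 within 1e-9 after construction.
- Stack/segment zero threshold 1e-12; equality threshold for the weight
  formula 1e-12; dissimilarity-matrix symmetry tolerance 1e-12.
- DP tie threshold 1e-15 on costs, then lexicographic labels.
- Problem sizes in tests and acceptance checks: 1,000-10,000 random column
  pairs for measure properties, 100-200 random instances for
  motif/ordering properties, N <= 8 for exhaustive ordering enumeration
  (2^(N-1) = 128 orders) — sizes at which the brute-force oracles are exact
  and the whole suite runs in seconds.

## Known limitations

- No motif alignment, shifting, trimming or reverse-complement handling;
  inputs must be pre-aligned and equal-length (or explicitly padded).
- No statistical significance for `D` (no permutation p-values); `D` is a
  descriptive dissimilarity.
- Log-odds PWMs are not accepted as input (no unambiguous inverse without
  a background model).
- The glyph font covers A-Z; other symbols in custom alphabets render as a
  box outline.
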