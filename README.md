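# motifdiff

Difference logos for sequence motifs: visualize and quantify *what differs*
between transcription-factor binding motifs (or any position-specific
profiles over DNA, RNA, protein or custom alphabets), pairwise and across
whole motif collections.

Classic sequence logos make single motifs legible, but two motifs of the
same factor — different cell lines, treatments or discovery pipelines — are
often so similar that their logos look interchangeable while their
position-specific distributions do not.  `motifdiff` targets exactly that
comparison problem, for people who produce or consume position weight
matrices: motif-discovery pipelines, ChIP-seq/SELEX analysts, and anyone
curating motifs against databases such as JASPAR.

## The method

A motif of length $L$ over alphabet $\mathcal{A}$ is a row-stochastic
matrix $p_{\ell,a}$ ($\ell = 1..L$).  Comparing two motifs $p$ and $q$
position by position, `motifdiff` draws a symbol stack per position:

- **Stack height** — the Jensen-Shannon divergence in bits,

  $$H_\ell = \tfrac12 \sum_a p_{\ell,a}\log_2\frac{p_{\ell,a}}{m_{\ell,a}}
           + \tfrac12 \sum_a q_{\ell,a}\log_2\frac{q_{\ell,a}}{m_{\ell,a}},
    \qquad m_{\ell,a} = \tfrac{p_{\ell,a}+q_{\ell,a}}{2},$$

  symmetric, bounded by 1 bit, zero iff the distributions agree.

- **Symbol heights** — signed shares $H_{\ell,a} = r_{\ell,a}\,H_\ell$ with
  the normalized probability difference
  $r_{\ell,a} = (p_{\ell,a}-q_{\ell,a}) / \sum_{a'} |p_{\ell,a'}-q_{\ell,a'}|$
  (zero when $p_\ell = q_\ell$).  Symbols more abundant in the first motif
  point up, symbols more abundant in the second point down; gains and
  losses balance at every position.

- **Scalar dissimilarity** — $D = \sum_{\ell=1}^{L} H_\ell$, used for
  comparing $N \ge 3$ motifs: all pairwise difference logos are arranged in
  an $N \times N$ grid with an empty diagonal and a shared ordinate, motifs
  ordered by the *optimal leaf order* of a hierarchical clustering on $D$
  (so similar motifs are neighbors), and cell backgrounds colored on a
  green (most similar) → red (most dissimilar) gradient.

Both measures are pluggable: alternative stack heights (sum of absolute
probability differences, information-content difference) and symbol
weights (raw difference) ship in a registry, and user functions can be
passed directly.

## Worked example

Create three random synthetic motifs and compare them:

```python
from motifdiff import DNA, random_motif
from motifdiff.io import write_tabular_matrix

for s in range(3):
    write_tabular_matrix(random_motif(DNA, 6, 0.5, seed=s, label=f"m{s}"), f"m{s}.tsv")
```

```bash
motifdiff grid m0.tsv m1.tsv m2.tsv --kind probabilities \
    --out grid.svg --export-dist D.tsv --export-tree tree.nwk
cat D.tsv
```

Output (rows/columns in input order; entries are $D$ in bits summed over
the 6 positions):

```
	m0	m1	m2
m0	0	2.14471072	1.189481041
m1	2.14471072	0	1.457279366
m2	1.189481041	1.457279366	0
```

`grid.svg` shows the 3×3 grid: `m0` and `m2` (smallest $D$, 1.19 bits) get
the greenest cells and are placed adjacent by the leaf ordering, as the
exported tree confirms:

```
(m1:1.07236,(m0:0.594741,m2:0.594741):0.477615);
```

A pairwise difference logo with its numeric sidecar:

```bash
motifdiff pair m0.tsv m1.tsv --kind probabilities \
    --out pair.svg --export-heights heights.tsv
head -4 heights.tsv
```

```
position	stack_height	H_A	H_C	H_G	H_T
1	0.296632	-0.058125	-0.0901911	0.0832377	0.0650784
2	0.148738	-0.0202841	-0.0540851	0.0479536	0.0264155
3	0.772366	0.282271	-0.336251	-0.0499318	0.103912
```

Position 3 differs most (0.77 bits): `m0` favors A where `m1` favors C
(positive `H_A`, negative `H_C`).  Swapping the two input motifs negates
every height.

Other subcommands: `motifdiff seqlogo` (classic logos from JASPAR, TSV or
FASTA-alignment input) and `motifdiff fixtures` (seeded synthetic test
data).  Everything is also available as a library API
(`build_difference_logo`, `build_grid`, `render_grid`, ...).

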