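"""Readers and writers for motifs, distance matrices, and cluster trees.

Supported inputs: JASPAR-style PFM text (counts), plain tabular matrices
(counts or probabilities, either orientation), and FASTA alignments of
equal-length sequences.  Outputs: JASPAR text, tabular TSV, TSV distance
matrices, and Newick trees.  Log-odds position weight matrices are not
accepted: without a declared background there is no unambiguous way back to
probabilities.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .compare import ClusterNode, ClusterTree, DissimilarityMatrix
from .errors import LengthMismatchError, MotifError, ParseError, ShapeError
from .model import (
    DNA,
    PROTEIN,
    RNA,
    Alphabet,
    CountMotif,
    ProbabilityMotif,
    sequences_to_counts,
    validate_probability_motif,
)


@dataclass(frozen=True)
class MotifFileRecord:
    """A labelled motif as read from a file."""

    label: str
    payload: object  # CountMotif or ProbabilityMotif
    source_format: str  # jaspar | tabular | fasta


def _infer_alphabet(symbols) -> Alphabet:
    syms = set(s.upper() for s in symbols)
    if syms == set("ACGT"):
        return DNA
    if syms == set("ACGU"):
        return RNA
    if syms == set(PROTEIN.symbols):
        return PROTEIN
    return Alphabet(tuple(sorted(syms)), name="custom")


_JASPAR_ROW = re.compile(r"^\s*(\S+)\s*\[?\s*([0-9.eE+\-\s]*?)\s*\]?\s*$")


def read_jaspar(source) -> list:
    """Parse JASPAR PFM text (path or raw text) into count-motif records.

    Accepts ``>ID name`` headers (multiple motifs per file) or a headerless
    single motif; symbol rows like ``A [ 3 5 0 ]`` with or without brackets,
    in any row order.  The alphabet is inferred from the row letters
    (ACGT -> DNA, ACGU -> RNA, the 20 amino acids -> protein).
    """
    text = _read_source(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty JASPAR input")
    blocks = []  # (label, row lines)
    current_label, current_rows = None, []
    fallback = _source_stem(source) or "motif"
    for ln in lines:
        if ln.lstrip().startswith(">"):
            if current_rows:
                blocks.append((current_label or fallback, current_rows))
            current_label, current_rows = ln.lstrip()[1:].strip() or fallback, []
        else:
            current_rows.append(ln)
    if current_rows:
        blocks.append((current_label or fallback, current_rows))
    if not blocks:
        raise ParseError("JASPAR input has headers but no matrix rows")

    records = []
    for label, rows in blocks:
        symbols, matrix = [], []
        width = None
        for ln in rows:
            m = _JASPAR_ROW.match(ln)
            if not m or not m.group(2).strip():
                raise ParseError(f"malformed JASPAR row in motif {label!r}: {ln!r}")
            sym = m.group(1).upper()
            if len(sym) != 1:
                raise ParseError(f"expected single-letter symbol, got {sym!r} in {label!r}")
            if sym in symbols:
                raise ParseError(f"duplicate symbol row {sym!r} in motif {label!r}")
            try:
                values = [float(tok) for tok in m.group(2).split()]
            except ValueError:
                raise ParseError(f"non-numeric value in JASPAR row: {ln!r}") from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ParseError(
                    f"ragged JASPAR rows in motif {label!r}: "
                    f"{len(values)} values vs {width}"
                )
            symbols.append(sym)
            matrix.append(values)
        arr = np.asarray(matrix)
        if not np.allclose(arr, np.round(arr)):
            raise ParseError(
                f"non-integer counts in motif {label!r}; probability matrices "
                "belong in tabular input, not JASPAR PFM"
            )
        alphabet = _infer_alphabet(symbols)
        order = [symbols.index(s) for s in alphabet.symbols]
        counts = np.round(arr[order]).astype(np.int64).T  # to L x |A|
        motif = CountMotif(alphabet=alphabet, counts=counts, label=label)
        records.append(MotifFileRecord(label=label, payload=motif, source_format="jaspar"))
    return records


def write_jaspar(records, path) -> None:
    """Write count motifs as JASPAR PFM text (bracketed rows)."""
    items = []
    for rec in records:
        motif = rec.payload if isinstance(rec, MotifFileRecord) else rec
        if not isinstance(motif, CountMotif):
            raise MotifError("JASPAR output requires count motifs")
        items.append(motif)
    with open(path, "w", encoding="ascii") as fh:
        for motif in items:
            fh.write(f">{motif.label}\n")
            for j, sym in enumerate(motif.alphabet.symbols):
                row = " ".join(str(int(v)) for v in motif.counts[:, j])
                fh.write(f"{sym} [ {row} ]\n")


def _read_source(source) -> str:
    if isinstance(source, os.PathLike):
        with open(source, encoding="utf-8") as fh:
            return fh.read()
    if isinstance(source, str):
        if "\n" in source:
            return source
        if os.path.exists(source):
            with open(source, encoding="utf-8") as fh:
                return fh.read()
        raise ParseError(f"no such file: {source}")
    raise MotifError(f"cannot read from {type(source).__name__}")


def _source_stem(source) -> str | None:
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        stem = os.path.splitext(os.path.basename(str(source)))[0]
        return stem or None
    return None


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_tabular_matrix(
    path,
    alphabet: Alphabet,
    orientation: str | None = None,
    kind: str = "counts",
    label: str | None = None,
    tolerance: float = 1e-4,
) -> MotifFileRecord:
    """Read a whitespace/tab-delimited motif matrix.

    ``orientation`` is ``symbols_by_positions`` (|A| rows) or
    ``positions_by_symbols`` (|A| columns).  A square |A| x |A| matrix is
    ambiguous and requires an explicit orientation — it is never guessed.
    Optional header row / label column are detected by non-numeric tokens.
    ``kind="probabilities"`` validates and renormalizes rows.
    """
    if orientation not in (None, "symbols_by_positions", "positions_by_symbols"):
        raise MotifError(f"unknown orientation {orientation!r}")
    if kind not in ("counts", "probabilities"):
        raise MotifError(f"kind must be 'counts' or 'probabilities', got {kind!r}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            toks = ln.split()
            if toks:
                rows.append(toks)
    if not rows:
        raise ParseError(f"empty matrix file: {path}")
    # drop a header row / label column of non-numeric tokens
    if any(not _is_number(t) for t in rows[0]):
        rows = rows[1:]
        if not rows:
            raise ParseError(f"matrix file has only a header: {path}")
    if any(not _is_number(r[0]) for r in rows):
        rows = [r[1:] for r in rows]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"ragged rows in matrix file: {path}")
    try:
        arr = np.asarray([[float(t) for t in r] for r in rows])
    except ValueError:
        raise ParseError(f"non-numeric entry in matrix file: {path}") from None

    a = alphabet.size
    fits_sbp = arr.shape[0] == a  # symbols_by_positions
    fits_pbs = arr.shape[1] == a  # positions_by_symbols
    if orientation is None:
        if fits_sbp and fits_pbs:
            raise ShapeError(
                f"{arr.shape} matrix is ambiguous for a {a}-symbol alphabet; "
                "pass orientation explicitly"
            )
        if fits_sbp:
            orientation = "symbols_by_positions"
        elif fits_pbs:
            orientation = "positions_by_symbols"
        else:
            raise ShapeError(
                f"matrix shape {arr.shape} incompatible with alphabet size {a} "
                "under both orientations"
            )
    if orientation == "symbols_by_positions":
        if not fits_sbp:
            raise ShapeError(
                f"matrix has {arr.shape[0]} rows, expected {a} (symbols_by_positions)"
            )
        arr = arr.T
    elif not fits_pbs:
        raise ShapeError(
            f"matrix has {arr.shape[1]} columns, expected {a} (positions_by_symbols)"
        )

    name = label or _source_stem(path) or "motif"
    if kind == "counts":
        payload = CountMotif(alphabet=alphabet, counts=arr, label=name)
    else:
        payload = validate_probability_motif(arr, alphabet, tolerance=tolerance, label=name)
    return MotifFileRecord(label=name, payload=payload, source_format="tabular")


def write_tabular_matrix(motif, path) -> None:
    """Write a motif as TSV: header of symbols, one row per position."""
    matrix = motif.counts if isinstance(motif, CountMotif) else motif.probs
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\t".join(motif.alphabet.symbols) + "\n")
        for row in matrix:
            if isinstance(motif, CountMotif):
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write("\t".join(format(v, ".6g") for v in row) + "\n")


def read_fasta_alignment(path, alphabet: Alphabet, unknown_policy: str = "skip") -> MotifFileRecord:
    """Tally an aligned FASTA file into a count motif.

    All records must share one length; gaps and ambiguity codes are skipped
    by default (``unknown_policy``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise LengthMismatchError(
                f"record {rec.id!r} in {path} has length {len(rec.seq)}, "
                f"expected {length}"
            )
    name = _source_stem(path) or "alignment"
    motif = sequences_to_counts(
        [str(rec.seq) for rec in records], alphabet, unknown_policy=unknown_policy, label=name
    )
    return MotifFileRecord(label=name, payload=motif, source_format="fasta")


def write_distance_matrix(matrix: DissimilarityMatrix, path) -> None:
    """Write a labelled TSV distance matrix (10 significant digits)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\t".join(("",) + matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def read_distance_matrix(path) -> DissimilarityMatrix:
    """Read a TSV distance matrix written by :func:`write_distance_matrix`."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"distance matrix file too short: {path}")
    header = lines[0].split("\t")
    labels = tuple(header[1:])
    values = []
    for ln in lines[1:]:
        toks = ln.split("\t")
        values.append([float(t) for t in toks[1:]])
    arr = np.asarray(values)
    # symmetrize away formatting round-off before the strict constructor
    arr = 0.5 * (arr + arr.T)
    np.fill_diagonal(arr, 0.0)
    return DissimilarityMatrix(labels=labels, values=arr)


def _newick_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick string for a cluster tree.

    Branch lengths use the ultrametric convention in which a node at merge
    height h sits at depth h/2, so a two-leaf tree merged at height h reads
    ``(A:h/2,B:h/2);``.
    """

    def render(node: ClusterNode, parent_height: float) -> str:
        length = (parent_height - node.height) / 2.0
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{format(length, '.6g')}"
        inner = ",".join(render(c, node.height) for c in (node.left, node.right))
        return f"({inner}):{format(length, '.6g')}"

    root = tree.root
    inner = ",".join(render(c, root.height) for c in (root.left, root.right))
    return f"({inner});"


def write_newick(tree: ClusterTree, path) -> None:
    """Serialize the cluster tree to a Newick file."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(tree_to_newick(tree) + "\n")
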