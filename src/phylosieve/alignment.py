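"""Alignment container and flat-file I/O.

The :class:`Alignment` is the object every data treatment in this package
transforms: a taxa-by-columns character matrix over a tagged alphabet
(20-state amino acids, a reduced recoding alphabet, or an arbitrary custom
alphabet), optionally carrying a :class:`PartitionMap` that records which
columns came from which concatenated marker.

Supermatrices are built with :func:`concatenate`; a taxon absent from a
marker is padded with ``'?'`` (fully missing) rather than ``'-'`` so that
likelihood computations treat those cells as uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

GAP = "-"
MISSING = "?"

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: amino-acid ambiguity/non-canonical codes collapsed to missing on recode
AA_AMBIGUOUS = "BZJUOX"

ALPHABETS = {
    "AA20": AA20,
    "SR4": "ACGT",
}


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment files or inconsistent matrices."""


@dataclass(frozen=True)
class PartitionMap:
    """Ordered half-open column intervals ``[start, end)`` tiling ``[0, L)``."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.entries:
            if start != pos or end <= start:
                raise ValueError(
                    f"partition {name!r} [{start},{end}) does not tile: expected start {pos}"
                )
            pos = end

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("marker\tstart\tend\n")
            for name, start, end in self.entries:
                fh.write(f"{name}\t{start}\t{end}\n")

    @classmethod
    def from_tsv(cls, path) -> "PartitionMap":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("marker"):
                raise AlignmentFormatError("partition TSV must have a 'marker' header line")
            for line in fh:
                if not line.strip():
                    continue
                name, start, end = line.rstrip("\n").split("\t")
                entries.append((name, int(start), int(end)))
        return cls(tuple(entries))

    def subset(self, kept_columns: np.ndarray) -> "PartitionMap":
        """Re-index after keeping ``kept_columns`` (sorted positions)."""
        kept = np.asarray(kept_columns)
        entries = []
        pos = 0
        for name, start, end in self.entries:
            n = int(np.count_nonzero((kept >= start) & (kept < end)))
            if n:
                entries.append((name, pos, pos + n))
                pos += n
        return PartitionMap(tuple(entries))


@dataclass
class Alignment:
    """Taxa-by-columns state matrix over a tagged alphabet.

    ``data`` is a 2-D numpy array of single characters (dtype ``<U1``);
    gaps are ``'-'`` and missing cells ``'?'``.
    """

    taxa: list[str]
    data: np.ndarray
    alphabet: str = "AA20"
    symbols: str | None = None
    partition: PartitionMap | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise AlignmentFormatError("data matrix does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon identifiers: {dupes}")
        if self.symbols is None:
            if self.alphabet not in ALPHABETS:
                raise AlignmentFormatError(
                    f"alphabet {self.alphabet!r} needs an explicit symbol set"
                )
            self.symbols = ALPHABETS[self.alphabet]
        allowed = set(self.symbols) | {GAP, MISSING} | set(AA_AMBIGUOUS)
        present = set(np.unique(self.data))
        bad = present - allowed
        if bad:
            raise AlignmentFormatError(f"symbols outside alphabet {self.alphabet}: {sorted(bad)}")
        if self.partition is not None and self.partition.total_length != self.n_cols:
            raise AlignmentFormatError("partition map does not tile the alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return int(self.data.shape[1])

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def take_columns(self, columns) -> "Alignment":
        cols = np.asarray(sorted(columns), dtype=int)
        part = self.partition.subset(cols) if self.partition is not None else None
        return Alignment(list(self.taxa), self.data[:, cols], self.alphabet, self.symbols, part)


def _records_to_alignment(records, alphabet: str, symbols: str | None) -> Alignment:
    taxa, rows = [], []
    length = None
    for name, seq in records:
        seq = seq.upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentFormatError(
                f"ragged alignment: taxon {name!r} has length {len(seq)}, expected {length}"
            )
        taxa.append(name)
        rows.append(list(seq))
    if not taxa:
        raise AlignmentFormatError("empty alignment file")
    return Alignment(taxa, np.array(rows, dtype="<U1"), alphabet, symbols)


def read_alignment(path, format: str = "fasta", alphabet: str = "AA20",
                   symbols: str | None = None) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Symbol case is normalised to upper; ragged rows and duplicate taxon
    names are rejected.
    """
    if format == "fasta":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip":
        records = _read_relaxed_phylip(path)
    else:
        raise AlignmentFormatError(f"unsupported format {format!r}")
    return _records_to_alignment(records, alphabet, symbols)


def _read_relaxed_phylip(path):
    # Relaxed dialect: whitespace-delimited names (<=250 chars), sequential
    # records, sequences may wrap over lines.  Biopython's phylip parser
    # enforces strict 10-character names, hence this small reader.
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 2:
        raise AlignmentFormatError("not a PHYLIP file: missing header")
    try:
        n_taxa, n_cols = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise AlignmentFormatError("not a PHYLIP file: non-numeric header") from exc
    records = []
    i = 2
    for _ in range(n_taxa):
        if i >= len(tokens):
            raise AlignmentFormatError("truncated PHYLIP file")
        name = tokens[i]
        if len(name) > 250:
            raise AlignmentFormatError(f"taxon name longer than 250 characters: {name[:30]}...")
        i += 1
        seq = ""
        while len(seq) < n_cols and i < len(tokens):
            seq += tokens[i]
            i += 1
        if len(seq) != n_cols:
            raise AlignmentFormatError(f"taxon {name!r}: sequence length {len(seq)} != {n_cols}")
        records.append((name, seq))
    return records


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    with open(path, "w") as fh:
        if format == "fasta":
            for i, name in enumerate(aln.taxa):
                fh.write(f">{name}\n{''.join(aln.data[i])}\n")
        elif format == "phylip":
            fh.write(f"{aln.n_taxa} {aln.n_cols}\n")
            for i, name in enumerate(aln.taxa):
                fh.write(f"{name}  {''.join(aln.data[i])}\n")
        else:
            raise AlignmentFormatError(f"unsupported format {format!r}")


def concatenate(alignments, names=None, taxon_union: bool = True):
    """Concatenate markers into a supermatrix with a partition map.

    The taxon set is the union over markers (in order of first appearance);
    a taxon missing from a marker is padded with ``'?'`` across that
    marker's interval.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to concatenate")
    alphabet = alignments[0].alphabet
    symbols = alignments[0].symbols
    for aln in alignments:
        if aln.alphabet != alphabet or aln.symbols != symbols:
            raise AlignmentFormatError("cannot concatenate alignments with mixed alphabets")
    if names is None:
        names = [f"marker{i+1}" for i in range(len(alignments))]
    if taxon_union:
        taxa: list[str] = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in taxa:
                    taxa.append(t)
    else:
        taxa = [t for t in alignments[0].taxa if all(t in a.taxa for a in alignments)]
        if not taxa:
            raise AlignmentFormatError("taxon intersection is empty")
    total = sum(a.n_cols for a in alignments)
    data = np.full((len(taxa), total), MISSING, dtype="<U1")
    entries = []
    pos = 0
    for name, aln in zip(names, alignments):
        idx = {t: i for i, t in enumerate(aln.taxa)}
        for j, t in enumerate(taxa):
            if t in idx:
                data[j, pos:pos + aln.n_cols] = aln.data[idx[t]]
        entries.append((name, pos, pos + aln.n_cols))
        pos += aln.n_cols
    part = PartitionMap(tuple(entries))
    return Alignment(taxa, data, alphabet, symbols, part), part


def subset_taxa(aln: Alignment, drop, prune_empty_cols: bool = False) -> Alignment:
    """Drop taxa (by identifier), optionally pruning all-gap/missing columns."""
    drop = set(drop)
    unknown = drop - set(aln.taxa)
    if unknown:
        raise KeyError(f"unknown taxa to drop: {sorted(unknown)}")
    keep = [i for i, t in enumerate(aln.taxa) if t not in drop]
    if not keep:
        raise ValueError("cannot drop all taxa")
    data = aln.data[keep]
    taxa = [aln.taxa[i] for i in keep]
    part = aln.partition
    if prune_empty_cols:
        informative = ~np.all((data == GAP) | (data == MISSING), axis=0)
        cols = np.nonzero(informative)[0]
        data = data[:, cols]
        if part is not None:
            part = part.subset(cols)
    return Alignment(taxa, data, aln.alphabet, aln.symbols, part)
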