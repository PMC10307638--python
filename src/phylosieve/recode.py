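"""Reduced-alphabet recoding of amino-acid alignments.

The built-in scheme is the four-state Susko–Roger grouping (SR4), which
pools the 20 amino acids into four bins of frequently-exchanged residues.
Collapsing the alphabet this way discards much of the compositional and
saturation-driven signal that pushes distant, convergently biased lineages
together, while retaining the deeper substitution signal.

The four SR4 bins are written as the symbols A, C, G and T so that recoded
alignments can flow through any 4-state (nucleotide-shaped) machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AA20, AA_AMBIGUOUS, GAP, MISSING, Alignment

#: Susko–Roger 4-state bins, in bin-symbol order A, C, G, T.
SR4_BINS = {
    "A": "AGNPST",
    "C": "CHWY",
    "G": "DEKQR",
    "T": "FILMV",
}


class RecodingError(ValueError):
    pass


@dataclass(frozen=True)
class RecodingScheme:
    name: str
    bins: dict[str, str]  # residue -> bin symbol

    def __post_init__(self):
        mapped = set(self.bins)
        if mapped != set(AA20):
            missing = set(AA20) - mapped
            extra = mapped - set(AA20)
            raise RecodingError(
                f"scheme {self.name!r} must map exactly the 20 amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    @property
    def k(self) -> int:
        return len(set(self.bins.values()))

    @property
    def symbols(self) -> str:
        return "".join(sorted(set(self.bins.values())))


def sr4_scheme() -> RecodingScheme:
    """The canonical four-state Susko–Roger scheme."""
    return RecodingScheme("SR4", {aa: sym for sym, group in SR4_BINS.items() for aa in group})


def scheme_from_tsv(path, name: str | None = None) -> RecodingScheme:
    """Load a custom scheme from a two-column TSV (residue, bin symbol)."""
    bins = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("residue"):
                continue
            residue, sym = line.split("\t")
            bins[residue.upper()] = sym
    return RecodingScheme(name or str(path), bins)


def recode(aln: Alignment, scheme: RecodingScheme | None = None) -> Alignment:
    """Apply a recoding scheme to an AA20 alignment.

    Gaps are preserved; ambiguity codes (B, Z, J, X) and the non-canonical
    U/O residues become ``'?'``.  Column count and taxon order are
    untouched.
    """
    if scheme is None:
        scheme = sr4_scheme()
    if aln.alphabet != "AA20":
        raise RecodingError(f"recoding requires an AA20 alignment, got {aln.alphabet!r}")
    table = dict(scheme.bins)
    table[GAP] = GAP
    table[MISSING] = MISSING
    for code in AA_AMBIGUOUS:
        table[code] = MISSING
    out = np.empty_like(aln.data)
    for sym in np.unique(aln.data):
        if sym not in table:
            i, j = np.argwhere(aln.data == sym)[0]
            raise RecodingError(
                f"unknown residue {sym!r} at taxon {aln.taxa[i]!r}, column {j}"
            )
        out[aln.data == sym] = table[sym]
    tag = "SR4" if scheme.name == "SR4" else f"CUSTOM-{scheme.k}"
    return Alignment(list(aln.taxa), out, tag, scheme.symbols, aln.partition)
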