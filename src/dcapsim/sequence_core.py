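"""Sequence representation, IUPAC semantics and standard-format I/O.

Coordinates are 1-based and inclusive at both ends everywhere in this
package, matching the convention of mitochondrial genome positions
(e.g. m.3460, m.11778, m.14484 on the rCRS).  Any half-open arithmetic
is internal and invisible at the interface.

Sequences are stored with their original case (lowercase is used by
convention to flag deliberately altered primer bases) but all
comparisons are case-insensitive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, List

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values, ambiguous_dna_complement

__all__ = [
    "NucSequence",
    "GenomicRegion",
    "IUPAC_CODES",
    "CONCRETE_BASES",
    "iupac_match",
    "iupac_set",
    "complement_code",
    "revcomp",
    "subsequence",
    "read_sequences",
    "write_fasta",
    "SequenceError",
    "ParseError",
    "RangeError",
]

# IUPAC nucleotide alphabet.  `ambiguous_dna_values` maps each code to the
# concrete bases it denotes (e.g. R -> "AG", N -> "ACGT").
IUPAC_CODES = frozenset(ambiguous_dna_values) | {"U"}
CONCRETE_BASES = frozenset("ACGT")

_COMPLEMENT = {k.upper(): v.upper() for k, v in ambiguous_dna_complement.items()}


class SequenceError(ValueError):
    """Invalid residues or malformed sequence objects."""


class ParseError(SequenceError):
    """A file or record could not be parsed in the requested format."""


class RangeError(SequenceError):
    """A region falls outside the bounds of its sequence."""


@lru_cache(maxsize=None)
def iupac_set(code: str) -> frozenset:
    """Concrete bases denoted by a single IUPAC code (T and U collapse)."""
    c = code.upper()
    if c == "U":
        c = "T"
    try:
        return frozenset(ambiguous_dna_values[c])
    except KeyError:
        raise SequenceError(f"not an IUPAC DNA code: {code!r}") from None


def iupac_match(base: str, pattern_code: str) -> bool:
    """True iff concrete ``base`` lies in the set denoted by ``pattern_code``.

    Matching is deliberately asymmetric: the pattern side expands
    degenerate codes, the base side must be a concrete A/C/G/T.
    A degenerate base on the base side is a contract violation.
    """
    b = base.upper()
    if b == "U":
        b = "T"
    if b not in CONCRETE_BASES:
        raise SequenceError(
            f"iupac_match requires a concrete base on the base side, got {base!r}"
        )
    return b in iupac_set(pattern_code)


def complement_code(code: str) -> str:
    """Complement of one IUPAC code, degeneracy preserved (N -> N, R -> Y)."""
    c = code.upper()
    if c == "U":
        c = "T"
    try:
        return _COMPLEMENT[c]
    except KeyError:
        raise SequenceError(f"not an IUPAC DNA code: {code!r}") from None


def _validate_residues(residues: str) -> None:
    if not residues:
        raise SequenceError("empty sequence is rejected")
    bad = set(residues.upper()) - IUPAC_CODES
    if bad:
        raise SequenceError(f"non-IUPAC residues: {sorted(bad)}")


@dataclass(frozen=True)
class NucSequence:
    """An IUPAC DNA sequence with identifier and topology.

    ``residues`` keeps the case it was given; ``upper`` caches the
    normalized form used for all matching.
    """

    id: str
    residues: str
    topology: str = "linear"  # "linear" | "circular"
    upper: str = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        _validate_residues(self.residues)
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"topology must be linear or circular: {self.topology!r}")
        object.__setattr__(self, "upper", self.residues.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def base(self, position: int) -> str:
        """Residue at a 1-based position (uppercase)."""
        if not 1 <= position <= len(self):
            raise RangeError(f"position {position} outside 1..{len(self)}")
        return self.upper[position - 1]

    def with_substitution(self, position: int, base: str) -> "NucSequence":
        """Copy with a single base replaced at a 1-based position."""
        if not 1 <= position <= len(self):
            raise RangeError(f"position {position} outside 1..{len(self)}")
        if base.upper() not in IUPAC_CODES:
            raise SequenceError(f"not an IUPAC code: {base!r}")
        res = self.residues[: position - 1] + base + self.residues[position:]
        return NucSequence(self.id, res, self.topology)


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive interval on a named sequence.

    ``start > end`` is the origin-wrapping form and is legal only on
    circular sequences.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.end < 1:
            raise RangeError("coordinates are 1-based; start/end must be >= 1")
        if self.strand not in ("+", "-"):
            raise SequenceError(f"strand must be + or -: {self.strand!r}")

    def length_on(self, seq_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        # wrap across the origin
        return seq_length - self.start + 1 + self.end


def revcomp(seq: NucSequence) -> NucSequence:
    """Reverse complement with degenerate codes mapped (case preserved)."""
    out = []
    for ch in reversed(seq.residues):
        up = ch.upper()
        if up == "U":
            up = "T"
        comp = _COMPLEMENT.get(up)
        if comp is None:
            raise SequenceError(f"not an IUPAC DNA code: {ch!r}")
        out.append(comp if ch.isupper() else comp.lower())
    return NucSequence(seq.id, "".join(out), seq.topology)


def revcomp_str(residues: str) -> str:
    """Reverse complement of a bare residue string (case preserved)."""
    return revcomp(NucSequence("_", residues)).residues


def subsequence(seq: NucSequence, region: GenomicRegion) -> NucSequence:
    """Extract a region; minus-strand requests return the reverse complement.

    Wrapping (start > end) is honoured on circular sequences only; the
    returned extract is always linear.
    """
    n = len(seq)
    if region.start > n or region.end > n:
        raise RangeError(
            f"region {region.start}-{region.end} outside 1..{n} of {seq.id!r}"
        )
    if region.start <= region.end:
        res = seq.residues[region.start - 1 : region.end]
    else:
        if not seq.is_circular:
            raise RangeError(
                f"start > end ({region.start} > {region.end}) requires circular topology"
            )
        res = seq.residues[region.start - 1 :] + seq.residues[: region.end]
    sub = NucSequence(f"{seq.id}:{region.start}-{region.end}", res, "linear")
    if region.strand == "-":
        sub = NucSequence(sub.id, revcomp(sub).residues, "linear")
    return sub


# ---------------------------------------------------------------------------
# Standard-format I/O (Biopython-backed)

def read_sequences(path, fmt: str = None) -> List[NucSequence]:
    """Read FASTA or GenBank records as NucSequence objects.

    ``fmt`` is "fasta" or "genbank"; when omitted it is guessed from the
    file extension.  GenBank topology (the LOCUS line) maps onto the
    sequence topology; FASTA records are linear.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "genbank" if ext in (".gb", ".gbk", ".genbank", ".gbff") else "fasta"
    if fmt not in ("fasta", "genbank"):
        raise ParseError(f"unsupported format: {fmt!r}")
    out: List[NucSequence] = []
    try:
        records = list(SeqIO.parse(path, fmt))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ParseError(f"could not parse {path} as {fmt}: {exc}") from exc
    for rec in records:
        topology = "linear"
        if fmt == "genbank":
            if rec.annotations.get("topology", "linear") == "circular":
                topology = "circular"
        try:
            out.append(NucSequence(rec.id, str(rec.seq), topology))
        except SequenceError as exc:
            raise ParseError(f"record {rec.id!r} in {path}: {exc}") from exc
    if not out:
        raise ParseError(f"no records parsed from {path} (format {fmt})")
    return out


def write_fasta(seqs: Iterable[NucSequence], path, width: int = 70) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns (case kept)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
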