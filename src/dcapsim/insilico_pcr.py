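"""Mismatch-tolerant primer binding and amplicon extraction.

The central convention is *primer override*: an amplicon's terminal
sequences are copies of the primers, not of the template.  This is the
mechanism by which deliberately altered (dCAPS) primers implant
restriction half-sites into a PCR product — the altered bases become
part of the product and, combined with the mutant allele immediately
downstream, complete a recognition site that the wild-type product
lacks.

Binding is combinatorial, not thermodynamic: a primer binds wherever its
footprint shows at most ``max_mismatch`` mismatches with none in the
3'-terminal ``protected_3prime`` bases.  Mismatches are counted with
IUPAC expansion on the primer side only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .sequence_core import (
    CONCRETE_BASES,
    GenomicRegion,
    NucSequence,
    SequenceError,
    iupac_set,
    revcomp_str,
)

__all__ = [
    "Primer",
    "PrimerBinding",
    "Amplicon",
    "find_bindings",
    "amplify",
    "multiplex_amplify",
    "primer_from_string",
    "primers_from_fasta",
    "DEFAULT_MAX_MISMATCH",
    "DEFAULT_PROTECTED_3PRIME",
    "DEFAULT_MAX_PRODUCT",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 3
DEFAULT_PROTECTED_3PRIME = 1
DEFAULT_MAX_PRODUCT = 5000
MIN_PRIMER_LENGTH = 15


@dataclass(frozen=True)
class Primer:
    """A 5'->3' oligo with deliberately altered positions flagged.

    ``altered_positions`` are 1-based within the primer and mark bases
    that intentionally mismatch the template (the lowercase letters of
    the lowercase-alteration convention).
    """

    name: str
    sequence_5to3: str
    altered_positions: frozenset = frozenset()

    def __post_init__(self):
        seq = self.sequence_5to3
        if len(seq) < MIN_PRIMER_LENGTH:
            raise SequenceError(
                f"primer {self.name!r}: length {len(seq)} < {MIN_PRIMER_LENGTH}"
            )
        NucSequence(self.name, seq)  # residue validation
        alt = frozenset(self.altered_positions)
        if any(p < 1 or p > len(seq) for p in alt):
            raise SequenceError(f"primer {self.name!r}: altered positions outside 1..{len(seq)}")
        object.__setattr__(self, "altered_positions", alt)

    def __len__(self) -> int:
        return len(self.sequence_5to3)

    @property
    def upper(self) -> str:
        return self.sequence_5to3.upper()

    def display(self) -> str:
        """Sequence with altered positions lowercased, everything else upper."""
        return "".join(
            c.lower() if (i + 1) in self.altered_positions else c.upper()
            for i, c in enumerate(self.sequence_5to3)
        )


def primer_from_string(name: str, seq: str) -> Primer:
    """Build a primer from a string in which lowercase marks alterations."""
    altered = frozenset(i + 1 for i, c in enumerate(seq) if c.islower())
    return Primer(name, seq, altered)


def primers_from_fasta(path) -> List[Primer]:
    """Read primers from FASTA; lowercase letters flag altered positions."""
    from .sequence_core import read_sequences

    return [primer_from_string(s.id, s.residues) for s in read_sequences(path, "fasta")]


@dataclass(frozen=True)
class PrimerBinding:
    """A primer footprint on the template top strand.

    ``strand`` "+" means the primer extends rightward (its 3' end at
    ``template_end``); "-" means the primer anneals to the top strand
    and extends leftward (3' end at ``template_start``).
    ``mismatch_positions`` are primer coordinates (1 = 5' end).
    """

    primer: Primer
    template_start: int
    template_end: int
    strand: str
    mismatch_count: int
    mismatch_positions: Tuple[int, ...]


def _base_matches_primer(template_base: str, primer_code: str) -> bool:
    # IUPAC expansion on the primer side only; degenerate template never matches
    if template_base not in CONCRETE_BASES:
        return False
    return template_base in iupac_set(primer_code)


def find_bindings(
    template: NucSequence,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    protected_3prime: int = DEFAULT_PROTECTED_3PRIME,
) -> List[PrimerBinding]:
    """All footprints on both strands within the mismatch budget.

    The 3'-terminal ``protected_3prime`` bases must match exactly —
    polymerases do not extend a mismatched 3' terminus efficiently, and
    the assay relies on this to keep bindings specific.  Only the
    terminal base is protected by default because dCAPS alterations
    legitimately sit at the penultimate position.
    """
    if max_mismatch < 0 or protected_3prime < 1:
        raise ValueError("max_mismatch >= 0 and protected_3prime >= 1 required")
    t = template.upper
    p = primer.upper
    L = len(p)
    n = len(t)
    if L > n:
        return []
    p_rc = revcomp_str(p).upper()
    protected_plus = set(range(L - protected_3prime, L))  # 0-based primer idx
    out: List[PrimerBinding] = []
    for a in range(0, n - L + 1):
        # plus strand: primer[i] vs template[a+i]
        mism: List[int] = []
        ok = True
        for i in range(L - 1, -1, -1):  # 3' end first: fail fast on protected bases
            if not _base_matches_primer(t[a + i], p[i]):
                if i in protected_plus:
                    ok = False
                    break
                mism.append(i + 1)
                if len(mism) > max_mismatch:
                    ok = False
                    break
        if ok:
            out.append(
                PrimerBinding(primer, a + 1, a + L, "+", len(mism), tuple(sorted(mism)))
            )
        # minus strand: revcomp(primer)[i] vs template[a+i]; primer idx = L-1-i
        mism = []
        ok = True
        for i in range(0, L):  # footprint left edge is the primer 3' end
            if not _base_matches_primer(t[a + i], p_rc[i]):
                pi = L - 1 - i  # 0-based primer index
                if pi in protected_plus:
                    ok = False
                    break
                mism.append(pi + 1)
                if len(mism) > max_mismatch:
                    ok = False
                    break
        if ok:
            out.append(
                PrimerBinding(primer, a + 1, a + L, "-", len(mism), tuple(sorted(mism)))
            )
    return out


@dataclass(frozen=True)
class Amplicon:
    """A PCR product whose ends are primer-defined, not template-defined."""

    sequence: NucSequence
    region: GenomicRegion
    fwd: Primer
    rev: Primer
    pair_name: str = ""
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _build_product(
    template: NucSequence, fwd_b: PrimerBinding, rev_b: PrimerBinding, pair_name: str
) -> Amplicon:
    """Assemble the product for a convergent (+ fwd, - rev) binding pair."""
    start, end = fwd_b.template_start, rev_b.template_end
    interior = template.residues[start - 1 : end]
    fwd, rev = fwd_b.primer, rev_b.primer
    seq = (
        fwd.display()
        + interior[len(fwd) : len(interior) - len(rev)]
        + revcomp_str(rev.display())
    )
    name = pair_name or f"{fwd.name}/{rev.name}"
    return Amplicon(
        sequence=NucSequence(f"{name}:{start}-{end}", seq, "linear"),
        region=GenomicRegion(template.id, start, end, "+"),
        fwd=fwd,
        rev=rev,
        pair_name=name,
        fwd_mismatches=fwd_b.mismatch_count,
        rev_mismatches=rev_b.mismatch_count,
    )


def amplify(
    template: NucSequence,
    fwd: Primer,
    rev: Primer,
    max_product: int = DEFAULT_MAX_PRODUCT,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    protected_3prime: int = DEFAULT_PROTECTED_3PRIME,
    pair_name: str = "",
) -> List[Amplicon]:
    """Every product of a convergent fwd/rev binding pair within ``max_product``.

    Both template orientations are considered: (fwd +, rev -) gives a
    top-strand product; (fwd -, rev +) gives the bottom-strand product,
    returned 5'->3' from the forward primer.  Zero products is a valid
    result, not an error.  Circular templates are scanned linearly
    (origin-spanning products are not modelled — the assay's products do
    not cross the origin).
    """
    fwd_bind = find_bindings(template, fwd, max_mismatch, protected_3prime)
    rev_bind = find_bindings(template, rev, max_mismatch, protected_3prime)
    products: List[Amplicon] = []
    for fb in fwd_bind:
        for rb in rev_bind:
            if fb.strand == "+" and rb.strand == "-":
                length = rb.template_end - fb.template_start + 1
                if len(fwd) + len(rev) <= length <= max_product:
                    products.append(_build_product(template, fb, rb, pair_name))
            elif fb.strand == "-" and rb.strand == "+":
                length = fb.template_end - rb.template_start + 1
                if len(fwd) + len(rev) <= length <= max_product:
                    # product on the bottom strand: build on revcomp coordinates
                    amp = _build_product_minus(template, fb, rb, pair_name)
                    products.append(amp)
    products.sort(key=lambda a: (a.region.start, a.region.end))
    return products


def _build_product_minus(
    template: NucSequence, fwd_b: PrimerBinding, rev_b: PrimerBinding, pair_name: str
) -> Amplicon:
    start, end = rev_b.template_start, fwd_b.template_end
    interior = revcomp_str(template.residues[start - 1 : end])
    fwd, rev = fwd_b.primer, rev_b.primer
    seq = (
        fwd.display()
        + interior[len(fwd) : len(interior) - len(rev)]
        + revcomp_str(rev.display())
    )
    name = pair_name or f"{fwd.name}/{rev.name}"
    return Amplicon(
        sequence=NucSequence(f"{name}:{start}-{end}(-)", seq, "linear"),
        region=GenomicRegion(template.id, start, end, "-"),
        fwd=fwd,
        rev=rev,
        pair_name=name,
        fwd_mismatches=fwd_b.mismatch_count,
        rev_mismatches=rev_b.mismatch_count,
    )


DEFAULT_GEL_SPACING = 20  # bp below which two products co-migrate on 2.5% agarose


def multiplex_amplify(
    template: NucSequence,
    pairs: Sequence[Tuple[str, Primer, Primer]],
    max_product: int = DEFAULT_MAX_PRODUCT,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    protected_3prime: int = DEFAULT_PROTECTED_3PRIME,
    min_spacing: int = DEFAULT_GEL_SPACING,
) -> List[Amplicon]:
    """Union of amplify() over named primer pairs.

    Logs a resolution warning when any two product lengths differ by
    less than ``min_spacing`` (they would be hard to separate on gel).
    """
    if not pairs:
        raise ValueError("at least one primer pair is required")
    products: List[Amplicon] = []
    for name, fwd, rev in pairs:
        products.extend(
            amplify(template, fwd, rev, max_product, max_mismatch, protected_3prime, name)
        )
    for i in range(len(products)):
        for j in range(i + 1, len(products)):
            a, b = products[i], products[j]
            if a.pair_name != b.pair_name and abs(a.length - b.length) < min_spacing:
                logger.warning(
                    "products %s (%d bp) and %s (%d bp) differ by < %d bp; "
                    "they may not resolve on gel",
                    a.pair_name, a.length, b.pair_name, b.length, min_spacing,
                )
    return products
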