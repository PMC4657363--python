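"""Restriction-enzyme model, degenerate-motif scanning and in-silico digestion.

The enzyme of interest throughout the built-in assay is MaeIII, which
recognizes the degenerate motif GTNAC and cleaves the top strand
immediately 5' of the first recognition base (↓GTnAC).  GTNAC is its own
reverse complement, so plus- and minus-strand matches share a footprint
and are reported once.

Fragment sizes are defined by top-strand cut points only: the fragment
arithmetic of a digested amplicon (e.g. 279 + 28 + 26 = 333 for the
mutant 3460 product) sums to the amplicon length exactly under
single-strand accounting; sticky-end overhangs are not modelled.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional

from .sequence_core import (
    CONCRETE_BASES,
    IUPAC_CODES,
    NucSequence,
    SequenceError,
    complement_code,
    iupac_set,
)

__all__ = [
    "RestrictionEnzyme",
    "CutSite",
    "Fragment",
    "find_sites",
    "digest_linear",
    "fragment_lengths",
    "load_enzyme_table",
    "bundled_enzymes",
    "get_enzyme",
    "MAEIII",
    "EnzymeTableError",
    "CircularDigestError",
]

logger = logging.getLogger(__name__)


class EnzymeTableError(ValueError):
    """Malformed enzyme-table row."""


class CircularDigestError(ValueError):
    """Digestion of circular substrates is unsupported by design."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A recognition motif with top/bottom cut offsets.

    ``cut_offset_top`` counts bases 5' of the first recognition base at
    which the top strand is cleaved: 0 means cleavage immediately before
    the first recognition base (the MaeIII convention); negative values
    move the cut inside the site (EcoRI G^AATTC has offset -1).
    ``cut_offset_bottom`` uses the mirrored convention from the
    recognition's 3' end.
    """

    name: str
    recognition: str
    cut_offset_top: int = 0
    cut_offset_bottom: int = 0

    def __post_init__(self):
        motif = self.recognition.upper()
        if len(motif) < 4:
            raise EnzymeTableError(
                f"{self.name}: recognition length must be >= 4, got {motif!r}"
            )
        bad = set(motif) - IUPAC_CODES
        if bad:
            raise EnzymeTableError(f"{self.name}: non-IUPAC motif characters {sorted(bad)}")
        object.__setattr__(self, "recognition", motif)

    def __len__(self) -> int:
        return len(self.recognition)

    @property
    def revcomp_motif(self) -> str:
        return "".join(complement_code(c) for c in reversed(self.recognition))

    @property
    def is_palindromic(self) -> bool:
        """True when the motif equals its reverse complement as an IUPAC set."""
        rc = self.revcomp_motif
        return all(iupac_set(a) == iupac_set(b) for a, b in zip(self.recognition, rc))


@dataclass(frozen=True)
class CutSite:
    """A located recognition site with its top-strand cleavage point.

    ``top_cut_after`` is the coordinate c such that the top strand is
    cleaved between c and c+1 (c = 0 means the cut falls before base 1,
    which releases no fragment on a linear substrate).
    """

    site_start: int
    strand: str
    top_cut_after: int


@dataclass(frozen=True)
class Fragment:
    """A digestion product, 1-based inclusive on the parent sequence."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _motif_matches_at(seq_upper: str, motif: str, start0: int) -> bool:
    """Window match of an IUPAC motif against a concrete-ish template.

    A degenerate base on the template side never matches (conservative:
    avoids phantom sites in low-quality references); a warning is logged
    once per scan by the caller.
    """
    for i, code in enumerate(motif):
        base = seq_upper[start0 + i]
        if base not in CONCRETE_BASES:
            return False
        if base not in iupac_set(code):
            return False
    return True


def find_sites(seq: NucSequence, enzyme: RestrictionEnzyme) -> List[CutSite]:
    """All recognition sites on either strand of a linear sequence.

    Sites are reported by the 1-based coordinate of their first
    recognition base on the top strand, sorted.  For palindromic motifs
    (MaeIII) the plus- and minus-strand matches at one footprint
    collapse into a single plus-strand site.
    """
    s = seq.upper
    m = len(enzyme)
    n = len(s)
    if set(s) - CONCRETE_BASES:
        logger.warning(
            "template %s contains degenerate bases; they never match a motif", seq.id
        )
    motif = enzyme.recognition
    rc_motif = enzyme.revcomp_motif
    palindromic = enzyme.is_palindromic
    sites: List[CutSite] = []
    for start0 in range(0, n - m + 1):
        pos = start0 + 1
        if _motif_matches_at(s, motif, start0):
            sites.append(
                CutSite(pos, "+", top_cut_after=pos - 1 - enzyme.cut_offset_top)
            )
        if not palindromic and _motif_matches_at(s, rc_motif, start0):
            # bottom-strand recognition: mirrored cut at the footprint's 3' side
            end = pos + m - 1
            sites.append(CutSite(pos, "-", top_cut_after=end + enzyme.cut_offset_top))
    sites.sort(key=lambda c: (c.site_start, c.strand))
    return sites


def digest_linear(seq: NucSequence, enzyme: RestrictionEnzyme) -> List[Fragment]:
    """Cut a linear sequence at every top-strand cut point.

    Fragments tile the parent 5'->3' without gaps or overlaps and their
    lengths sum exactly to the sequence length.  Duplicate cut points
    (overlapping sites) collapse; cuts falling outside (0, len) are
    ignored as they release nothing.
    """
    if seq.is_circular:
        raise CircularDigestError(
            "circular digestion is unsupported; every assay substrate is a linear "
            "amplicon or insert"
        )
    n = len(seq)
    cuts = sorted(
        {c.top_cut_after for c in find_sites(seq, enzyme) if 0 < c.top_cut_after < n}
    )
    bounds = [0] + cuts + [n]
    return [Fragment(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])]


def fragment_lengths(seq: NucSequence, enzyme: RestrictionEnzyme) -> List[int]:
    """Digest and return lengths 5'->3' (convenience wrapper)."""
    return [f.length for f in digest_linear(seq, enzyme)]


# ---------------------------------------------------------------------------
# Enzyme tables

def load_enzyme_table(path) -> List[RestrictionEnzyme]:
    """Parse a minimal REBASE-inspired TSV of enzymes.

    Columns: name, recognition, cut_offset_top, cut_offset_bottom.
    Lines starting with '#' are comments.  An empty table is legal.
    """
    enzymes: List[RestrictionEnzyme] = []
    with open(os.fspath(path)) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise EnzymeTableError(f"row {lineno}: expected 4 columns, got {len(row)}")
            name, motif, top, bottom = (c.strip() for c in row[:4])
            try:
                enz = RestrictionEnzyme(name, motif, int(top), int(bottom))
            except (ValueError, SequenceError) as exc:
                raise EnzymeTableError(f"row {lineno} ({name!r}): {exc}") from exc
            enzymes.append(enz)
    return enzymes


def bundled_enzymes() -> List[RestrictionEnzyme]:
    """The packaged default enzyme table (includes MaeIII)."""
    ref = resources.files("dcapsim.data").joinpath("enzymes.tsv")
    with resources.as_file(ref) as path:
        return load_enzyme_table(path)


def get_enzyme(name: str, enzymes: Optional[List[RestrictionEnzyme]] = None) -> RestrictionEnzyme:
    pool = enzymes if enzymes is not None else bundled_enzymes()
    for e in pool:
        if e.name.lower() == name.lower():
            return e
    raise KeyError(f"enzyme {name!r} not in table")


#: MaeIII: ↓GTnAC — cleaves immediately 5' of the recognition sequence.
MAEIII = RestrictionEnzyme("MaeIII", "GTNAC", 0, 0)
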