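"""dCAPS design: minimal primer alterations creating allele-discriminating sites.

The design problem: given a SNP and a restriction enzyme, place the
enzyme's recognition motif so that it overlaps the SNP and is completed
by the *mutant* allele but not the wild-type one.  Bases of the motif
that fall under a nearby primer may be supplied by deliberate primer
alterations (which the PCR product inherits by primer override); bases
outside the primer must be matched by the template itself.  A placement
needing zero alterations is a *natural* allele-gained site (CAPS); one
needing a few is the *derived* (dCAPS) case.

The discriminating position is the SNP base itself, which is always
template-provided and never altered — altering it would destroy allele
specificity.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .sequence_core import (
    NucSequence,
    SequenceError,
    iupac_match,
    iupac_set,
    subsequence,
    GenomicRegion,
)
from .restriction import RestrictionEnzyme, digest_linear, find_sites
from .insilico_pcr import Primer, amplify

__all__ = [
    "SnpTarget",
    "DesignConstraints",
    "DesignCandidate",
    "MultiplexSelection",
    "classify_natural_site_change",
    "design_mismatch_primer",
    "select_multiplex_enzyme",
    "validate_candidate",
    "simulate_candidate",
    "load_snp_table",
    "load_snps_vcf",
    "TargetValidationError",
]

logger = logging.getLogger(__name__)


class TargetValidationError(ValueError):
    """SNP target disagrees with the loaded reference."""


@dataclass(frozen=True)
class SnpTarget:
    """A single-nucleotide target: 1-based position with ref/alt alleles."""

    name: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        for a in (self.ref_allele, self.alt_allele):
            if a.upper() not in "ACGT" or len(a) != 1:
                raise SequenceError(f"{self.name}: alleles must be single A/C/G/T, got {a!r}")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())

    def validate_against(self, ref: NucSequence) -> None:
        found = ref.base(self.position)
        if found != self.ref_allele:
            raise TargetValidationError(
                f"{self.name}: reference has {found} at {self.position}, "
                f"expected {self.ref_allele}"
            )


@dataclass(frozen=True)
class DesignConstraints:
    """Search bounds for the mismatch-primer design.

    Defaults admit classic dCAPS geometries: up to two alterations, only
    the 3'-terminal base protected (alterations at the penultimate and
    -3/-4 positions are legitimate design moves), primer 3' end within
    3 bases of the SNP.
    """

    primer_length_range: Tuple[int, int] = (18, 36)
    max_alterations: int = 2
    protected_3prime: int = 1
    max_3prime_gap: int = 3
    min_diagnostic_delta: int = 20
    multiplex_min_spacing: int = 20

    def __post_init__(self):
        if self.max_alterations < 0 or self.protected_3prime < 1:
            raise ValueError("max_alterations >= 0 and protected_3prime >= 1 required")
        lo, hi = self.primer_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid primer_length_range")


@dataclass(frozen=True)
class DesignCandidate:
    """One feasible (placement, primer) design for a SNP/enzyme combination.

    ``site_start`` is the reference coordinate of the first motif base of
    the designed placement.  ``predicted_fragments`` maps genotype
    ("ref"/"alt") to digestion fragment lengths of the simulated product.
    """

    target: SnpTarget
    enzyme: RestrictionEnzyme
    primer: Primer
    orientation: str  # "forward" | "reverse"
    mode: str  # "natural" | "engineered"
    site_with: str  # "alt_allele" | "ref_allele"
    site_start: int
    anchor_3prime: int  # top-strand coordinate of the primer's 3' terminus
    predicted_fragments: Dict[str, Tuple[int, ...]]
    n_alterations: int
    product_size: int


def _window_sites(seq: NucSequence, enzyme: RestrictionEnzyme, center: int) -> frozenset:
    L = len(enzyme)
    lo = max(1, center - 2 * L)
    hi = min(len(seq), center + 2 * L)
    win = subsequence(seq, GenomicRegion(seq.id, lo, hi))
    return frozenset((c.site_start + lo - 1, c.strand) for c in find_sites(win, enzyme))


def classify_natural_site_change(
    ref: NucSequence, target: SnpTarget, enzyme: RestrictionEnzyme
) -> str:
    """Does the alt allele gain or lose a recognition site near the SNP?

    Compares the enzyme's site set in a window around the SNP between
    the two alleles; returns "gained", "lost" or "none".
    """
    target.validate_against(ref)
    if target.alt_allele == target.ref_allele:
        return "none"
    alt_seq = ref.with_substitution(target.position, target.alt_allele)
    ref_sites = _window_sites(ref, enzyme, target.position)
    alt_sites = _window_sites(alt_seq, enzyme, target.position)
    if alt_sites > ref_sites or (alt_sites - ref_sites and not (ref_sites - alt_sites)):
        return "gained"
    if ref_sites > alt_sites or (ref_sites - alt_sites and not (alt_sites - ref_sites)):
        return "lost"
    return "none"


def _pick_altered_base(code: str, ref_base: str) -> str:
    """Concrete base satisfying a motif code, different from the template base."""
    for b in "ACGT":
        if b != ref_base and b in iupac_set(code):
            return b
    raise SequenceError(f"no base satisfies motif code {code} other than {ref_base}")


def _enumerate_placements(
    ref: NucSequence,
    target: SnpTarget,
    enzyme: RestrictionEnzyme,
    constraints: DesignConstraints,
    orientation: str,
):
    """Yield raw feasible designs for one primer orientation.

    Coordinates are on the reference top strand throughout; for the
    reverse orientation the primer footprint lies 3' of the SNP (its 3'
    terminus at the footprint's left edge) and primer-supplied bases are
    those at or right of that terminus.
    """
    p = target.position
    L = len(enzyme)
    motif = enzyme.recognition
    n = len(ref)
    min_len, max_len = constraints.primer_length_range
    for gap in range(1, constraints.max_3prime_gap + 1):
        if orientation == "forward":
            e = p - gap  # primer 3' terminus (top-strand coordinate)
            if e < 1:
                continue
        else:
            e = p + gap
            if e > n:
                continue
        for s in range(p - L + 1, p + 1):
            if s < 1 or s + L - 1 > n:
                continue
            window = list(range(s, s + L))

            def primer_covers(i: int) -> bool:
                return i <= e if orientation == "forward" else i >= e

            # the SNP must be template-provided
            if primer_covers(p):
                continue
            ok = True
            alterations: List[int] = []  # top-strand coordinates to alter
            for i, code in zip(window, motif):
                base = target.alt_allele if i == p else ref.base(i)
                if iupac_match(base, code):
                    continue
                if i == p:
                    ok = False  # alt allele itself does not fit the motif here
                    break
                if not primer_covers(i):
                    ok = False  # template-side mismatch cannot be engineered
                    break
                alterations.append(i)
            if not ok or len(alterations) > constraints.max_alterations:
                continue
            # protected 3' bases may not be altered
            prot = constraints.protected_3prime
            if orientation == "forward":
                if any(i > e - prot for i in alterations):
                    continue
            else:
                if any(i < e + prot for i in alterations):
                    continue
            # discrimination: with the engineered bases in place, the ref
            # allele must NOT complete the motif
            ref_matches = True
            for i, code in zip(window, motif):
                base = ref.base(i) if i not in alterations else _pick_altered_base(
                    code, ref.base(i)
                )
                if not iupac_match(base, code):
                    ref_matches = False
                    break
            if ref_matches:
                continue
            # primer geometry: cover the 3' terminus through all alterations,
            # then extend the 5' tail until the allele-dependent cut releases
            # a fragment big enough to shift the principal band visibly on
            # gel (this is what makes the diagnostic delta resolvable)
            cut_after = s - 1 - enzyme.cut_offset_top
            if orientation == "forward":
                left_needed = min([e] + alterations)
                plen = max(min_len, e - left_needed + 1)
                plen = max(plen, constraints.min_diagnostic_delta + (e - cut_after))
                plen = min(plen, max_len)
                start5 = e - plen + 1
                if start5 < 1 or plen < e - left_needed + 1:
                    continue
            else:
                right_needed = max([e] + alterations)
                plen = max(min_len, right_needed - e + 1)
                plen = max(plen, constraints.min_diagnostic_delta + (cut_after - e + 1))
                plen = min(plen, max_len)
                end5 = e + plen - 1
                if end5 > n or plen < right_needed - e + 1:
                    continue
            yield {
                "orientation": orientation,
                "site_start": s,
                "e": e,
                "alterations": sorted(alterations),
                "plen": plen,
            }


def _make_primer(
    ref: NucSequence,
    target: SnpTarget,
    enzyme: RestrictionEnzyme,
    raw: dict,
) -> Primer:
    motif = enzyme.recognition
    s = raw["site_start"]
    e, plen = raw["e"], raw["plen"]
    code_at = {s + k: motif[k] for k in range(len(motif))}
    if raw["orientation"] == "forward":
        start5 = e - plen + 1
        bases = []
        altered = []
        for idx, i in enumerate(range(start5, e + 1), start=1):
            refb = ref.base(i)
            if i in raw["alterations"]:
                bases.append(_pick_altered_base(code_at[i], refb).lower())
                altered.append(idx)
            else:
                bases.append(refb)
        name = f"{target.name}-{enzyme.name}-F"
        return Primer(name, "".join(bases), frozenset(altered))
    # reverse: footprint [e, e+plen-1] on top strand; primer is its revcomp
    from .sequence_core import complement_code

    end3 = e + plen - 1
    bases = []
    altered = []
    for idx, i in enumerate(range(end3, e - 1, -1), start=1):  # primer 5'->3'
        refb = ref.base(i)
        if i in raw["alterations"]:
            top = _pick_altered_base(code_at[i], refb)
            bases.append(complement_code(top).lower())
            altered.append(idx)
        else:
            bases.append(complement_code(refb))
    name = f"{target.name}-{enzyme.name}-R"
    return Primer(name, "".join(bases), frozenset(altered))


def _template_primer(ref: NucSequence, start: int, end: int, strand: str, name: str) -> Primer:
    """A plain (unaltered) primer copied from the template."""
    seg = subsequence(ref, GenomicRegion(ref.id, start, end, strand))
    return Primer(name, seg.residues)


def simulate_candidate(
    ref: NucSequence,
    candidate_primer: Primer,
    orientation: str,
    anchor_3prime: int,
    target: SnpTarget,
    enzyme: RestrictionEnzyme,
    product_size: int = 200,
    mate_length: int = 20,
) -> Dict[str, Tuple[int, ...]]:
    """Round-trip a design through in-silico PCR and digestion per genotype.

    ``anchor_3prime`` is the top-strand coordinate of the designed
    primer's 3' terminus.  A plain template mate primer is placed to
    give a product of ``product_size`` bases.  Returns genotype ->
    fragment lengths.
    """
    plen = len(candidate_primer)
    n = len(ref)
    if orientation == "forward":
        amp_start = anchor_3prime - plen + 1
        amp_end = amp_start + product_size - 1
        if amp_end > n:
            raise ValueError(f"product of {product_size} bp does not fit the reference")
        mate = _template_primer(ref, amp_end - mate_length + 1, amp_end, "-",
                                f"{candidate_primer.name}-mate")
        fwd, rev = candidate_primer, mate
    else:
        amp_end = anchor_3prime + plen - 1
        amp_start = amp_end - product_size + 1
        if amp_start < 1:
            raise ValueError(f"product of {product_size} bp does not fit the reference")
        mate = _template_primer(ref, amp_start, amp_start + mate_length - 1, "+",
                                f"{candidate_primer.name}-mate")
        fwd, rev = mate, candidate_primer
    out: Dict[str, Tuple[int, ...]] = {}
    for geno, allele in (("ref", target.ref_allele), ("alt", target.alt_allele)):
        template = ref.with_substitution(target.position, allele)
        products = [
            a
            for a in amplify(template, fwd, rev, max_product=product_size + mate_length)
            if a.region.start == amp_start and a.region.end == amp_end
        ]
        if len(products) != 1:
            raise ValueError(
                f"expected exactly one product at {amp_start}-{amp_end}, "
                f"got {len(products)}"
            )
        out[geno] = tuple(f.length for f in digest_linear(products[0].sequence, enzyme))
    return out


def design_mismatch_primer(
    ref: NucSequence,
    target: SnpTarget,
    enzyme: RestrictionEnzyme,
    constraints: DesignConstraints = DesignConstraints(),
    product_size: int = 200,
) -> List[DesignCandidate]:
    """Enumerate allele-discriminating primer designs for one SNP and enzyme.

    Every placement of the recognition motif overlapping the SNP is
    tried in both primer orientations; for each feasible placement the
    minimal alteration set is computed and the design is verified by
    simulating PCR + digestion on both alleles.  Candidates are sorted
    by (number of alterations, primer length, alterations closest to the
    5' end preferred) — extension fidelity favours alterations far from
    the 3' terminus.  An empty list means no feasible design.
    """
    target.validate_against(ref)
    seen = set()
    candidates: List[DesignCandidate] = []
    for orientation in ("forward", "reverse"):
        for raw in _enumerate_placements(ref, target, enzyme, constraints, orientation):
            key = (orientation, raw["site_start"], tuple(raw["alterations"]), raw["plen"])
            if key in seen:
                continue
            seen.add(key)
            primer = _make_primer(ref, target, enzyme, raw)
            try:
                frags = simulate_candidate(
                    ref, primer, orientation, raw["e"], target, enzyme, product_size
                )
            except ValueError as exc:
                logger.debug("placement at %d dropped: %s", raw["site_start"], exc)
                continue
            if Counter(frags["ref"]) == Counter(frags["alt"]):
                continue  # discrimination guarantee
            n_alt = len(raw["alterations"])
            candidates.append(
                DesignCandidate(
                    target=target,
                    enzyme=enzyme,
                    primer=primer,
                    orientation=orientation,
                    mode="natural" if n_alt == 0 else "engineered",
                    site_with="alt_allele",
                    site_start=raw["site_start"],
                    anchor_3prime=raw["e"],
                    predicted_fragments=frags,
                    n_alterations=n_alt,
                    product_size=product_size,
                )
            )

    def sort_key(c: DesignCandidate):
        if c.primer.altered_positions:
            # distance of the closest alteration to the 3' terminus; larger is safer
            min_dist = min(len(c.primer) - p for p in c.primer.altered_positions)
        else:
            min_dist = len(c.primer)
        return (c.n_alterations, len(c.primer), -min_dist, c.site_start)

    candidates.sort(key=sort_key)
    return candidates


@dataclass
class ValidationReport:
    """Simulation-backed audit of one design candidate."""

    candidate: DesignCandidate
    constant_sites: List[int]          # allele-independent site starts (amplicon coords)
    diagnostic_sites: List[int]        # allele-dependent site starts
    confounding_sites: List[int]       # allele-dependent sites away from the SNP
    has_internal_control: bool
    diagnostic_delta: int
    meets_delta: bool


def validate_candidate(
    candidate: DesignCandidate,
    ref: NucSequence,
    constraints: DesignConstraints = DesignConstraints(),
) -> ValidationReport:
    """Audit a candidate: internal control, confounders, diagnostic delta.

    A *constant* site (cut on both alleles) inside the product can serve
    as an internal control of complete digestion; allele-dependent sites
    that do not overlap the designed placement are confounders.
    """
    target = candidate.target
    enzyme = candidate.enzyme
    plen = len(candidate.primer)
    frags_ref = candidate.predicted_fragments["ref"]
    frags_alt = candidate.predicted_fragments["alt"]
    product = candidate.product_size
    # cut positions (amplicon coords) per genotype, from fragment tilings
    def cuts(frags):
        acc, out = 0, []
        for f in frags[:-1]:
            acc += f
            out.append(acc)
        return set(out)

    ref_cuts, alt_cuts = cuts(frags_ref), cuts(frags_alt)
    constant = sorted(ref_cuts & alt_cuts)
    dependent = sorted(ref_cuts ^ alt_cuts)
    # the designed site produces the allele-dependent cut nearest the SNP end
    confounding: List[int] = []
    if candidate.orientation == "forward":
        snp_amp = plen + (target.position - candidate.anchor_3prime)
    else:
        snp_amp = product - (plen + (candidate.anchor_3prime - target.position))
    for c in dependent:
        if abs(c - snp_amp) > len(enzyme) + abs(enzyme.cut_offset_top):
            confounding.append(c)
    delta = abs(max(frags_ref) - max(frags_alt))
    return ValidationReport(
        candidate=candidate,
        constant_sites=constant,
        diagnostic_sites=[c for c in dependent if c not in confounding],
        confounding_sites=confounding,
        has_internal_control=bool(constant),
        diagnostic_delta=delta,
        meets_delta=delta >= constraints.min_diagnostic_delta,
    )


@dataclass
class MultiplexSelection:
    """Outcome of the one-enzyme-for-all-targets search."""

    solved: bool
    enzyme: Optional[RestrictionEnzyme]
    candidates: Dict[str, DesignCandidate] = field(default_factory=dict)
    product_sizes: Dict[str, int] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)  # enzyme -> reason

    def __bool__(self) -> bool:
        return self.solved


def _assign_product_sizes(
    ref: NucSequence,
    cands: Dict[str, DesignCandidate],
    constraints: DesignConstraints,
    options: Sequence[int] = tuple(range(150, 501, 50)),
    band_floor: int = 50,
) -> Optional[Dict[str, int]]:
    """Backtracking assignment of product sizes with gel-resolvable spacing.

    Two bands (>= band_floor) from different targets must differ by at
    least ``multiplex_min_spacing`` in every genotype combination.
    """
    names = list(cands)
    spacing = constraints.multiplex_min_spacing

    def bands_for(name: str, size: int) -> Optional[List[int]]:
        c = cands[name]
        try:
            frags = simulate_candidate(
                ref, c.primer, c.orientation, c.anchor_3prime, c.target,
                c.enzyme, product_size=size,
            )
        except ValueError:
            return None
        if Counter(frags["ref"]) == Counter(frags["alt"]):
            return None
        out = {f for fs in frags.values() for f in fs if f >= band_floor}
        out.add(size)  # the undigested product must resolve too
        return sorted(out)

    def ok(bands_a: List[int], bands_b: List[int]) -> bool:
        return all(abs(a - b) >= spacing for a in bands_a for b in bands_b)

    assignment: Dict[str, int] = {}
    chosen_bands: Dict[str, List[int]] = {}

    def backtrack(i: int) -> bool:
        if i == len(names):
            return True
        name = names[i]
        for size in options:
            bands = bands_for(name, size)
            if bands is None:
                continue
            if all(ok(bands, chosen_bands[m]) for m in assignment):
                assignment[name] = size
                chosen_bands[name] = bands
                if backtrack(i + 1):
                    return True
                del assignment[name]
                del chosen_bands[name]
        return False

    return assignment if backtrack(0) else None


def select_multiplex_enzyme(
    ref: NucSequence,
    targets: Sequence[SnpTarget],
    enzymes: Sequence[RestrictionEnzyme],
    constraints: DesignConstraints = DesignConstraints(),
) -> MultiplexSelection:
    """Pick one enzyme serving every target with minimal total alterations.

    Enzymes that give at least one natural (zero-alteration) candidate
    are preferred; ties break toward more natural candidates, then the
    shorter recognition motif.  Product sizes are assigned so that all
    informative bands are separable on gel.
    """
    if not targets:
        raise ValueError("at least one target is required")
    failures: Dict[str, str] = {}
    scored = []
    for enz in enzymes:
        per_target: Dict[str, DesignCandidate] = {}
        reason = None
        for t in targets:
            cands = design_mismatch_primer(ref, t, enz, constraints)
            if not cands:
                reason = f"no feasible design for target {t.name}"
                break
            per_target[t.name] = cands[0]
        if reason:
            failures[enz.name] = reason
            continue
        sizes = _assign_product_sizes(ref, per_target, constraints)
        if sizes is None:
            failures[enz.name] = "no gel-resolvable product-size assignment"
            continue
        total_alt = sum(c.n_alterations for c in per_target.values())
        n_natural = sum(1 for c in per_target.values() if c.mode == "natural")
        scored.append(
            ((0 if n_natural else 1, total_alt, -n_natural, len(enz)), enz, per_target, sizes)
        )
    if not scored:
        return MultiplexSelection(False, None, failures=failures)
    scored.sort(key=lambda x: x[0])
    _, enz, per_target, sizes = scored[0]
    return MultiplexSelection(True, enz, per_target, sizes, failures)


# ---------------------------------------------------------------------------
# SNP target I/O

def load_snp_table(path) -> List[SnpTarget]:
    """TSV with columns name, position, ref, alt ('#' comments allowed)."""
    out: List[SnpTarget] = []
    with open(os.fspath(path)) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ValueError(f"row {lineno}: expected 4 columns (name, position, ref, alt)")
            name, pos, ref_a, alt_a = (c.strip() for c in row[:4])
            out.append(SnpTarget(name, int(pos), ref_a, alt_a))
    return out


def load_snps_vcf(path) -> List[SnpTarget]:
    """Single-sample VCF, SNVs only; positions taken verbatim (1-based)."""
    from cyvcf2 import VCF

    out: List[SnpTarget] = []
    for var in VCF(os.fspath(path)):
        if not var.is_snp:
            continue
        alt = var.ALT[0] if var.ALT else None
        if alt is None or len(var.REF) != 1 or len(alt) != 1:
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}{var.REF}>{alt}"
        out.append(SnpTarget(name, var.POS, var.REF, alt))
    return out
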