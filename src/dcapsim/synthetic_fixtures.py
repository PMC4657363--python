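"""Download-free pseudo-templates with exactly specified assay geometry.

Real mitochondrial reference data cannot be assumed to be present, so
these generators build random sequences in which primer footprints,
allele-dependent recognition sites and constant control sites are
implanted at exact offsets, and every *accidental* occurrence of the
enzyme motif is repaired away.  The resulting templates reproduce the
full expected fragment arithmetic of the built-in assay — products of
333/164/236 bp digesting to {307,26} / {279,28,26} / {135,29} /
{205,31} — without any download.

Two tiers are produced:

* :func:`make_lhon_like_reference` — a ~3 kb linear pseudo-reference
  with locally generated pseudo-primers, used by the fast test tier.
* :func:`make_rcrs_emulation` — a synthetic 16,569-bp circular genome
  that embeds the assay's published primer sequences at the mito-genome
  coordinates implied by the published product sizes (SNPs at 3460, 11778
  and 14484; constant control site at 3736).  It is an emulation for
  offline use, not the real NC_012920.1; only the primer footprints,
  implanted sites and SNP context are meaningful — all filler is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence_core import NucSequence, iupac_set, revcomp_str
from .restriction import MAEIII, RestrictionEnzyme, digest_linear, find_sites
from .insilico_pcr import Primer, amplify, primer_from_string
from .dcaps_design import SnpTarget

__all__ = [
    "GeometrySpec",
    "LocusSpec",
    "InfeasibleGeometryError",
    "make_amplicon_with_geometry",
    "make_lhon_like_reference",
    "make_rcrs_emulation",
    "RCRS_EMULATION_LENGTH",
]

RCRS_EMULATION_LENGTH = 16569


class InfeasibleGeometryError(ValueError):
    """The requested geometry cannot be realised (overlapping demands)."""


def _concrete_motif(enzyme: RestrictionEnzyme) -> str:
    """One concrete instance of the recognition motif (first base per code)."""
    return "".join(sorted(iupac_set(c))[0] for c in enzyme.recognition)


def _random_bases(rng: np.random.Generator, n: int) -> List[str]:
    return list(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _repair_pass(
    bases: List[str],
    enzyme: RestrictionEnzyme,
    allowed_starts: frozenset,
    protected: frozenset,
) -> bool:
    """Break one disallowed motif occurrence; True if a change was made."""
    seq = NucSequence("_scan", "".join(bases))
    for site in find_sites(seq, enzyme):
        if site.site_start in allowed_starts:
            continue
        motif = enzyme.recognition if site.strand == "+" else enzyme.revcomp_motif
        for j, code in enumerate(motif):
            pos0 = site.site_start - 1 + j
            if pos0 in protected:
                continue
            options = [b for b in "ACGT" if b not in iupac_set(code)]
            if not options:  # an N position cannot break a match
                continue
            bases[pos0] = options[0]
            return True
        raise InfeasibleGeometryError(
            f"accidental {enzyme.name} site at {site.site_start} lies entirely "
            "within protected positions"
        )
    return False


def _repair_all(
    bases: List[str],
    enzyme: RestrictionEnzyme,
    allowed_starts: frozenset,
    protected: frozenset,
    max_iter: int = 500,
) -> None:
    for _ in range(max_iter):
        if not _repair_pass(bases, enzyme, allowed_starts, protected):
            return
    raise InfeasibleGeometryError("motif repair did not converge")


# ---------------------------------------------------------------------------
# Single-amplicon generator

@dataclass(frozen=True)
class GeometrySpec:
    """Demands on one generated amplicon.

    ``site_cut_offsets`` are the distances from the 5' end at which
    top-strand cuts must fall (cut between offset and offset+1); the
    enzyme motif must occur at exactly those placements and nowhere
    else.  ``forbidden_motifs`` must not occur anywhere.
    """

    total_length: int
    fwd: Primer
    rev: Primer
    site_cut_offsets: Tuple[int, ...] = ()
    forbidden_motifs: Tuple[str, ...] = ()
    seed: int = 0


def make_amplicon_with_geometry(
    spec: GeometrySpec, enzyme: RestrictionEnzyme = MAEIII
) -> NucSequence:
    """Deterministic sequence of ``total_length`` realising the spec exactly.

    The sequence starts with the forward primer and ends with the
    reverse complement of the reverse primer; digestion by ``enzyme``
    cuts exactly at ``site_cut_offsets``.
    """
    n = spec.total_length
    fwd = spec.fwd.upper
    rev_rc = revcomp_str(spec.rev.upper).upper()
    if len(fwd) + len(rev_rc) > n:
        raise InfeasibleGeometryError("primers do not fit in total_length")
    for off in spec.site_cut_offsets:
        if not 0 < off < n:
            raise InfeasibleGeometryError(f"cut offset {off} outside (0, {n})")
    motif = _concrete_motif(enzyme)
    L = len(motif)
    site_starts0 = []  # 0-based first recognition base
    for off in sorted(spec.site_cut_offsets):
        start0 = off + enzyme.cut_offset_top  # cut_after = start - 1 - offset_top
        if start0 < 0 or start0 + L > n:
            raise InfeasibleGeometryError(f"site for cut at {off} falls outside the sequence")
        site_starts0.append(start0)
    for a, b in zip(site_starts0, site_starts0[1:]):
        if b < a + L:
            raise InfeasibleGeometryError("recognition sites overlap")

    rng = np.random.default_rng(spec.seed)
    bases = _random_bases(rng, n)
    bases[: len(fwd)] = list(fwd)
    bases[n - len(rev_rc):] = list(rev_rc)
    protected = set(range(len(fwd))) | set(range(n - len(rev_rc), n))
    for s0 in site_starts0:
        for j, code in enumerate(motif):
            pos0 = s0 + j
            if pos0 in protected:
                if bases[pos0] not in iupac_set(enzyme.recognition[j]):
                    raise InfeasibleGeometryError(
                        f"site at {s0 + 1} overlaps a primer whose base "
                        f"{bases[pos0]} cannot match motif position {j + 1}"
                    )
            else:
                bases[pos0] = code
        protected |= set(range(s0, s0 + L))

    allowed = frozenset(s0 + 1 for s0 in site_starts0)
    _repair_all(bases, enzyme, allowed, frozenset(protected))
    for fm in spec.forbidden_motifs:
        _repair_all(bases, RestrictionEnzyme("_forbidden", fm, 0, 0), frozenset(),
                    frozenset(protected))
    _repair_all(bases, enzyme, allowed, frozenset(protected))

    seq = NucSequence(f"geom-{spec.seed}", "".join(bases))
    got = [f.end for f in digest_linear(seq, enzyme)[:-1]]
    if got != sorted(spec.site_cut_offsets):
        raise InfeasibleGeometryError(
            f"verification failed: cuts at {got}, wanted {sorted(spec.site_cut_offsets)}"
        )
    return seq


# ---------------------------------------------------------------------------
# Reference generators

@dataclass(frozen=True)
class LocusSpec:
    """Placement of one assay locus inside a generated reference.

    Amplicon coordinates are 1-based from the product's 5' end; the
    designed (allele-dependent) site is given by the motif instance that
    the *mutant* product shows, with the SNP inside it and any
    primer-altered positions listed.  ``template_at_alterations`` gives
    the wild-type template base under each altered primer position.
    """

    name: str
    amp_start: int          # reference coordinate of the product's first base
    amp_len: int
    fwd_len: int
    rev_len: int
    snp_amp_pos: int        # amplicon coordinate of the SNP
    ref_allele: str
    alt_allele: str
    site_amp_start: int     # amplicon coordinate of the designed site's first base
    site_instance: str      # concrete motif the mutant product shows (e.g. GTCAC)
    altered_amp_positions: Tuple[int, ...] = ()
    template_at_alterations: Tuple[str, ...] = ()
    control_site_amp_starts: Tuple[int, ...] = ()
    fwd_seq: Optional[str] = None   # published primer (lowercase = altered); None = derive
    rev_seq: Optional[str] = None

    @property
    def amp_end(self) -> int:
        return self.amp_start + self.amp_len - 1

    def to_ref(self, amp_pos: int) -> int:
        return self.amp_start + amp_pos - 1


def _expected_fragments(
    locus: LocusSpec, enzyme: RestrictionEnzyme, genotype: str
) -> Tuple[int, ...]:
    cuts = [s - 1 - enzyme.cut_offset_top for s in locus.control_site_amp_starts]
    if genotype == "alt":
        cuts.append(locus.site_amp_start - 1 - enzyme.cut_offset_top)
    bounds = [0] + sorted(c for c in cuts if 0 < c < locus.amp_len) + [locus.amp_len]
    return tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]))


def _build_reference(
    ref_id: str,
    total_length: int,
    topology: str,
    loci: Sequence[LocusSpec],
    enzyme: RestrictionEnzyme,
    seed: int,
    max_attempts: int = 32,
) -> Tuple[NucSequence, List[SnpTarget], Dict[str, Tuple[Primer, Primer]]]:
    last_error: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        try:
            return _build_reference_once(ref_id, total_length, topology, loci, enzyme, rng)
        except InfeasibleGeometryError as exc:
            last_error = exc
    raise InfeasibleGeometryError(f"could not realise reference geometry: {last_error}")


def _build_reference_once(ref_id, total_length, topology, loci, enzyme, rng):
    bases = _random_bases(rng, total_length)
    protected: set = set()
    control_starts: set = set()     # allowed in every variant
    natural_starts: Dict[str, int] = {}   # locus -> site start allowed on its variant
    primers: Dict[str, Tuple[Primer, Primer]] = {}
    snps: List[SnpTarget] = []

    motif = enzyme.recognition
    for locus in loci:
        if locus.amp_end > total_length:
            raise InfeasibleGeometryError(f"{locus.name}: amplicon exceeds reference")
        # ---- forward primer footprint (template version)
        fwd_start0 = locus.amp_start - 1
        if locus.fwd_seq is not None:
            fwd_primer = primer_from_string(f"{locus.name}F", locus.fwd_seq)
            tpl = list(fwd_primer.upper)
            for amp_pos, ref_base in zip(
                locus.altered_amp_positions, locus.template_at_alterations
            ):
                tpl[amp_pos - 1] = ref_base.upper()
            bases[fwd_start0 : fwd_start0 + len(tpl)] = tpl
        else:
            # random footprint; fix altered template bases afterwards
            fwd_primer = None
        # ---- reverse primer footprint
        rev_start0 = locus.amp_end - locus.rev_len
        if locus.rev_seq is not None:
            rev_primer = primer_from_string(f"{locus.name}R", locus.rev_seq)
            bases[rev_start0 : rev_start0 + locus.rev_len] = list(
                revcomp_str(rev_primer.upper).upper()
            )
        else:
            rev_primer = None
        # ---- designed allele-dependent site
        s0 = locus.to_ref(locus.site_amp_start) - 1
        altered_ref0 = {locus.to_ref(p) - 1 for p in locus.altered_amp_positions}
        alt_by_amp = dict(zip(locus.altered_amp_positions, locus.template_at_alterations))
        for j, inst in enumerate(locus.site_instance):
            amp_pos = locus.site_amp_start + j
            pos0 = locus.to_ref(amp_pos) - 1
            if amp_pos == locus.snp_amp_pos:
                if inst.upper() != locus.alt_allele:
                    raise InfeasibleGeometryError(
                        f"{locus.name}: site instance base {inst} at the SNP must be "
                        f"the alt allele {locus.alt_allele}"
                    )
                bases[pos0] = locus.ref_allele
            elif amp_pos in alt_by_amp:
                tb = alt_by_amp[amp_pos].upper()
                if tb in iupac_set(motif[j]) and motif[j] != "N":
                    raise InfeasibleGeometryError(
                        f"{locus.name}: template base {tb} under altered primer "
                        f"position {amp_pos} already matches the motif"
                    )
                bases[pos0] = tb
            else:
                bases[pos0] = inst.upper()
        # ---- constant control sites
        inst = _concrete_motif(enzyme)
        for cs in locus.control_site_amp_starts:
            c0 = locus.to_ref(cs) - 1
            if any(
                c0 + j in range(rev_start0, rev_start0 + locus.rev_len)
                and locus.rev_seq is not None
                for j in range(len(inst))
            ):
                raise InfeasibleGeometryError(
                    f"{locus.name}: control site overlaps a fixed reverse primer"
                )
            bases[c0 : c0 + len(inst)] = list(inst)
            control_starts.add(c0 + 1)
            protected |= set(range(c0, c0 + len(inst)))

        # ---- derive pseudo-primers from the finished template if not given
        if fwd_primer is None:
            # ensure altered template bases mismatch the motif instance
            for amp_pos, ref_base in zip(
                locus.altered_amp_positions, locus.template_at_alterations
            ):
                bases[locus.to_ref(amp_pos) - 1] = ref_base.upper()
            footprint = "".join(bases[fwd_start0 : fwd_start0 + locus.fwd_len])
            pseq = list(footprint)
            for amp_pos in locus.altered_amp_positions:
                j = amp_pos - locus.site_amp_start
                pseq[amp_pos - 1] = locus.site_instance[j].lower()
            fwd_primer = primer_from_string(f"{locus.name}F", "".join(pseq))
        if rev_primer is None:
            footprint = "".join(bases[rev_start0 : rev_start0 + locus.rev_len])
            rev_primer = primer_from_string(f"{locus.name}R", revcomp_str(footprint).upper())

        primers[locus.name] = (fwd_primer, rev_primer)
        snps.append(
            SnpTarget(locus.name, locus.to_ref(locus.snp_amp_pos),
                      locus.ref_allele, locus.alt_allele)
        )
        if not locus.altered_amp_positions:
            natural_starts[locus.name] = s0 + 1
        protected |= set(range(fwd_start0, fwd_start0 + locus.fwd_len))
        protected |= set(range(rev_start0, rev_start0 + locus.rev_len))
        protected |= set(range(s0, s0 + len(motif)))

    # ---- genome-wide repair on the wild type and every single-mutant variant
    protected_f = frozenset(protected)
    for _ in range(500):
        changed = False
        if _repair_pass(bases, enzyme, frozenset(control_starts), protected_f):
            changed = True
        for locus in loci:
            variant = list(bases)
            variant[loci_pos0(locus)] = locus.alt_allele
            allowed = set(control_starts)
            if locus.name in natural_starts:
                allowed.add(natural_starts[locus.name])
            before = "".join(variant)
            if _repair_pass(variant, enzyme, frozenset(allowed), protected_f):
                # copy the repair back to the master (the SNP itself is protected)
                for i, (a, b) in enumerate(zip(before, variant)):
                    if a != b:
                        bases[i] = b
                changed = True
        if not changed:
            break
    else:
        raise InfeasibleGeometryError("variant-aware repair did not converge")

    ref = NucSequence(ref_id, "".join(bases), topology)
    _verify_reference(ref, loci, primers, enzyme)
    return ref, snps, primers


def loci_pos0(locus: LocusSpec) -> int:
    return locus.to_ref(locus.snp_amp_pos) - 1


def _verify_reference(ref, loci, primers, enzyme) -> None:
    """Run the real pipeline per locus/genotype; raise on any deviation."""
    for locus in loci:
        fwd, rev = primers[locus.name]
        for genotype in ("ref", "alt"):
            allele = locus.ref_allele if genotype == "ref" else locus.alt_allele
            template = ref.with_substitution(locus.to_ref(locus.snp_amp_pos), allele)
            products = amplify(template, fwd, rev)
            hits = [
                a for a in products
                if a.region.start == locus.amp_start and a.region.end == locus.amp_end
            ]
            if len(products) != len(hits) or len(hits) != 1:
                raise InfeasibleGeometryError(
                    f"{locus.name}/{genotype}: expected one product at "
                    f"{locus.amp_start}-{locus.amp_end}, got "
                    f"{[(a.region.start, a.region.end) for a in products]}"
                )
            want = _expected_fragments(locus, enzyme, genotype)
            got = tuple(f.length for f in digest_linear(hits[0].sequence, enzyme))
            if got != want:
                raise InfeasibleGeometryError(
                    f"{locus.name}/{genotype}: fragments {got}, wanted {want}"
                )


# ---------------------------------------------------------------------------
# The two shipped references

def _lhon_like_loci() -> List[LocusSpec]:
    # Geometry mirrors the built-in assay's fragment table on pseudo-loci.
    return [
        LocusSpec(
            name="pseudo-3460", amp_start=201, amp_len=333, fwd_len=31, rev_len=20,
            snp_amp_pos=32, ref_allele="G", alt_allele="A",
            site_amp_start=29, site_instance="GTCAC",
            altered_amp_positions=(30,), template_at_alterations=("A",),
            control_site_amp_starts=(308,),
        ),
        LocusSpec(
            name="pseudo-11778", amp_start=1201, amp_len=164, fwd_len=21, rev_len=21,
            snp_amp_pos=33, ref_allele="G", alt_allele="A",
            site_amp_start=30, site_instance="GTCAC",
        ),
        LocusSpec(
            name="pseudo-14484", amp_start=2201, amp_len=236, fwd_len=35, rev_len=22,
            snp_amp_pos=36, ref_allele="T", alt_allele="C",
            site_amp_start=32, site_instance="GTCAC",
            altered_amp_positions=(32, 33), template_at_alterations=("A", "C"),
        ),
    ]


def make_lhon_like_reference(
    seed: int = 0,
) -> Tuple[NucSequence, List[SnpTarget], Dict[str, Tuple[Primer, Primer]]]:
    """A ~3 kb linear pseudo-reference reproducing the whole fragment table.

    Returns (reference, SNP records, per-locus primer pairs).  Different
    seeds give different sequences with identical fragment tables.
    """
    return _build_reference(
        f"lhon-fixture-{seed}", 3000, "linear", _lhon_like_loci(), MAEIII, seed
    )


def _rcrs_emulation_loci() -> List[LocusSpec]:
    from .assay_engine import LHON_PUBLISHED_PRIMERS  # the published primer set

    f3460, r3460 = LHON_PUBLISHED_PRIMERS["3460"]
    f11778, r11778 = LHON_PUBLISHED_PRIMERS["11778"]
    f14484, r14484 = LHON_PUBLISHED_PRIMERS["14484"]
    return [
        LocusSpec(
            name="G3460A", amp_start=3429, amp_len=333,
            fwd_len=len(f3460), rev_len=len(r3460),
            snp_amp_pos=32, ref_allele="G", alt_allele="A",
            site_amp_start=29, site_instance="GTCAC",
            altered_amp_positions=(30,), template_at_alterations=("A",),
            control_site_amp_starts=(308,),   # reference position 3736
            fwd_seq=f3460, rev_seq=r3460,
        ),
        LocusSpec(
            name="G11778A", amp_start=11746, amp_len=164,
            fwd_len=len(f11778), rev_len=len(r11778),
            snp_amp_pos=33, ref_allele="G", alt_allele="A",
            site_amp_start=30, site_instance="GTCAC",
            fwd_seq=f11778, rev_seq=r11778,
        ),
        LocusSpec(
            name="T14484C", amp_start=14449, amp_len=236,
            fwd_len=len(f14484), rev_len=len(r14484),
            snp_amp_pos=36, ref_allele="T", alt_allele="C",
            site_amp_start=32, site_instance="GTCAC",
            altered_amp_positions=(32, 33), template_at_alterations=("A", "C"),
            fwd_seq=f14484, rev_seq=r14484,
        ),
    ]


def make_rcrs_emulation(
    seed: int = 0,
) -> Tuple[NucSequence, List[SnpTarget], Dict[str, Tuple[Primer, Primer]]]:
    """SYNTHETIC stand-in for the human mitochondrial reference genome.

    A 16,569-bp circular sequence in which the built-in assay's published
    primers, the constant MaeIII control site at position 3736 and the
    three SNP contexts (3460, 11778, 14484) are embedded at the
    coordinates implied by the published product sizes; everything else
    is seeded random filler, repaired to be free of accidental MaeIII
    sites.  This is NOT the real NC_012920.1 — it reproduces only the
    assay-relevant geometry, for fully offline simulation and testing.
    """
    return _build_reference(
        "rCRS-synthetic-emulation", RCRS_EMULATION_LENGTH, "circular",
        _rcrs_emulation_loci(), MAEIII, seed,
    )
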