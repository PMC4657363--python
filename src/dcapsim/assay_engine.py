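"""The multiplex PCR-RFLP assay as a first-class object.

Built around the three-locus mitochondrial assay for Leber's hereditary
optic neuropathy: one multiplex PCR (products of 333, 164 and 236 bp for
the 3460, 11778 and 14484 loci) followed by a single MaeIII digestion.
The mutant alleles introduce MaeIII sites — naturally at 11778,
primer-engineered at 3460 and 14484 — so each mutation shortens its
product's principal band (307→279, 164→135, 236→205).  A constant
MaeIII site inside the 3460 product (reference position 3736) releases a
26-bp fragment on every template and serves as the internal control of
complete digestion: a lane still showing the full-length 333-bp product
was under-digested and must not be genotyped.

Heteroplasmy (mutant and wild-type genomes coexisting) shows as
simultaneous cut and uncut diagnostic bands; the mutant molar fraction
is estimated from their intensities under mass-proportional staining.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .sequence_core import GenomicRegion, NucSequence, subsequence
from .restriction import (
    MAEIII,
    RestrictionEnzyme,
    digest_linear,
    fragment_lengths,
    get_enzyme,
)
from .insilico_pcr import Amplicon, Primer, amplify, primer_from_string
from .dcaps_design import SnpTarget
from .gel_sim import Band, GelModel, Lane, LaneObservation, detect_bands, lane_from_fragments

__all__ = [
    "AssayTarget",
    "AssayDefinition",
    "GenotypeCall",
    "TargetCall",
    "ControlMix",
    "LaneObservation",
    "builtin_lhon_assay",
    "expected_fragment_table",
    "simulate_lane",
    "call_genotype",
    "estimate_heteroplasmy",
    "heteroplasmy_detection_limit",
    "build_controls",
    "simulate_mix_lane",
    "observation_from_sizes",
    "load_assay_definition",
    "assay_from_definition",
    "save_assay_definition",
    "read_lane_csv",
    "write_lane_csv",
    "AssayConstructionError",
    "LHON_PUBLISHED_PRIMERS",
    "LHON_SNP_TARGETS",
    "DEFAULT_SIZE_TOLERANCE",
    "SMALL_BAND_FLOOR",
]

#: Published primer sequences of the built-in assay (lowercase letters are
#: the deliberate alterations that, combined with the mutant allele,
#: complete a MaeIII site in the PCR product).
LHON_PUBLISHED_PRIMERS: Dict[str, Tuple[str, str]] = {
    "3460": ("CCCCTACGGGCTACTACAACCCTTCGCTGtC", "GATAGTAGAATGATGGCTAG"),
    "11778": ("AGCAAACTCAAACTACGAACG", "TTACTAGCACAGAGAGTTCTC"),
    "14484": ("AATAGCCATCGCTGTAGTATATCCAAAGACAgtCA", "GTGCGAGAATAATGATGTATGC"),
}

LHON_SNP_TARGETS: Tuple[SnpTarget, ...] = (
    SnpTarget("G3460A", 3460, "G", "A"),
    SnpTarget("G11778A", 11778, "G", "A"),
    SnpTarget("T14484C", 14484, "T", "C"),
)

LHON_PRODUCT_SIZES: Dict[str, int] = {"G3460A": 333, "G11778A": 164, "T14484C": 236}
LHON_CONTROL_FRAGMENT = 26

DEFAULT_SIZE_TOLERANCE = 3   # +/- bp for band matching
SMALL_BAND_FLOOR = 50        # bands below this corroborate but are never required


class AssayConstructionError(ValueError):
    """Simulation disagrees with the declared assay (wrong reference?)."""


@dataclass(frozen=True)
class AssayTarget:
    """One locus of the multiplex: SNP, primer pair and cut geometry."""

    target: SnpTarget
    fwd: Primer
    rev: Primer
    product_size: int
    region: GenomicRegion
    ref_fragments: Tuple[int, ...]
    alt_fragments: Tuple[int, ...]
    constant_cuts: Tuple[int, ...]   # allele-independent cut points (product coords)
    diagnostic_cut: Optional[int]    # the allele-dependent cut point

    @property
    def ref_principal(self) -> int:
        return max(self.ref_fragments)

    @property
    def alt_principal(self) -> int:
        return max(self.alt_fragments)


@dataclass(frozen=True)
class AssayDefinition:
    """A validated multiplex PCR-RFLP assay bound to a reference."""

    name: str
    enzyme: RestrictionEnzyme
    targets: Tuple[AssayTarget, ...]
    reference: NucSequence
    control_fragment: Optional[int]
    size_tolerance: int = DEFAULT_SIZE_TOLERANCE

    def target_by_name(self, name: str) -> AssayTarget:
        for t in self.targets:
            if t.target.name == name:
                return t
        raise KeyError(name)

    @property
    def target_names(self) -> List[str]:
        return [t.target.name for t in self.targets]


def _cut_points(fragments: Sequence[int]) -> List[int]:
    acc, out = 0, []
    for f in fragments[:-1]:
        acc += f
        out.append(acc)
    return out


def _construct_target(
    ref: NucSequence,
    snp: SnpTarget,
    fwd: Primer,
    rev: Primer,
    enzyme: RestrictionEnzyme,
    max_product: int = 5000,
) -> AssayTarget:
    snp.validate_against(ref)
    products_by_geno: Dict[str, Amplicon] = {}
    for geno, allele in (("ref", snp.ref_allele), ("alt", snp.alt_allele)):
        template = ref.with_substitution(snp.position, allele)
        products = amplify(template, fwd, rev, max_product=max_product)
        containing = [
            a for a in products if a.region.start <= snp.position <= a.region.end
        ]
        if len(containing) != 1:
            raise AssayConstructionError(
                f"{snp.name}: expected one product containing the SNP, "
                f"got {len(containing)} (of {len(products)} total)"
            )
        products_by_geno[geno] = containing[0]
    ref_amp = products_by_geno["ref"]
    alt_amp = products_by_geno["alt"]
    if ref_amp.length != alt_amp.length:
        raise AssayConstructionError(f"{snp.name}: allele-dependent product length")
    ref_frags = tuple(fragment_lengths(ref_amp.sequence, enzyme))
    alt_frags = tuple(fragment_lengths(alt_amp.sequence, enzyme))
    ref_cuts, alt_cuts = set(_cut_points(ref_frags)), set(_cut_points(alt_frags))
    constant = tuple(sorted(ref_cuts & alt_cuts))
    dependent = sorted(ref_cuts ^ alt_cuts)
    if len(dependent) != 1:
        raise AssayConstructionError(
            f"{snp.name}: expected exactly one allele-dependent cut, got {dependent}"
        )
    return AssayTarget(
        target=snp, fwd=fwd, rev=rev,
        product_size=ref_amp.length, region=ref_amp.region,
        ref_fragments=ref_frags, alt_fragments=alt_frags,
        constant_cuts=constant, diagnostic_cut=dependent[0],
    )


def builtin_lhon_assay(
    ref: NucSequence,
    targets: Optional[Sequence[SnpTarget]] = None,
    primers: Optional[Dict[str, Tuple[Primer, Primer]]] = None,
    enzyme: RestrictionEnzyme = MAEIII,
) -> AssayDefinition:
    """Construct and verify the built-in three-locus MaeIII assay.

    On the default arguments the published primers and canonical SNP
    coordinates are used and the construction is verified by simulation:
    product sizes must be 333/164/236 and the internal control fragment
    26 bp; disagreement raises (guarding against a wrong reference).
    ``targets``/``primers`` may be overridden to bind the same assay
    geometry on a fixture reference.
    """
    if targets is None:
        targets = LHON_SNP_TARGETS
    if primers is None:
        primers = {
            t.name: (
                primer_from_string(f"{key}F", LHON_PUBLISHED_PRIMERS[key][0]),
                primer_from_string(f"{key}R", LHON_PUBLISHED_PRIMERS[key][1]),
            )
            for t, key in zip(targets, ("3460", "11778", "14484"))
        }
    assay_targets = []
    for snp in targets:
        fwd, rev = primers[snp.name]
        assay_targets.append(_construct_target(ref, snp, fwd, rev, enzyme))
    sizes = sorted(t.product_size for t in assay_targets)
    if sizes != sorted(LHON_PRODUCT_SIZES.values()):
        raise AssayConstructionError(
            f"product sizes {sizes} disagree with the expected "
            f"{sorted(LHON_PRODUCT_SIZES.values())}"
        )
    control_frag = _control_fragment(assay_targets)
    if control_frag != LHON_CONTROL_FRAGMENT:
        raise AssayConstructionError(
            f"internal control fragment {control_frag} != {LHON_CONTROL_FRAGMENT}"
        )
    return AssayDefinition(
        name="LHON-MaeIII", enzyme=enzyme, targets=tuple(assay_targets),
        reference=ref, control_fragment=control_frag,
    )


def _control_fragment(targets: Sequence[AssayTarget]) -> Optional[int]:
    """The fragment released by a constant cut (smallest, across targets)."""
    candidates = []
    for t in targets:
        for cut in t.constant_cuts:
            candidates.append(min(cut, t.product_size - cut))
    return min(candidates) if candidates else None


# ---------------------------------------------------------------------------
# Fragment tables and lane simulation

def expected_fragment_table(
    assay: AssayDefinition, genotypes: Dict[str, str]
) -> Dict[str, List[int]]:
    """Per-target digestion fragment lists for a genotype assignment.

    ``genotypes`` maps target name to "ref" or "alt".  The result also
    carries an "uncut" entry listing the undigested product sizes.
    """
    out: Dict[str, List[int]] = {"uncut": [t.product_size for t in assay.targets]}
    for t in assay.targets:
        geno = genotypes.get(t.target.name, "ref")
        if geno not in ("ref", "alt"):
            raise ValueError(f"{t.target.name}: genotype must be ref or alt, got {geno!r}")
        frags = t.ref_fragments if geno == "ref" else t.alt_fragments
        out[t.target.name] = list(frags)
    return out


def simulate_lane(
    assay: AssayDefinition,
    genotypes: Dict[str, str],
    model: GelModel = GelModel(),
    heteroplasmy: Optional[Dict[str, float]] = None,
    digested: bool = True,
) -> LaneObservation:
    """Forward-model one gel lane (equimolar products by default).

    ``heteroplasmy`` maps a target name to the mutant molar fraction f;
    that product contributes its ref fragments at molarity 1-f and its
    alt fragments at f.
    """
    heteroplasmy = heteroplasmy or {}
    fragments: List[Tuple[float, float]] = []
    for t in assay.targets:
        name = t.target.name
        if not digested:
            fragments.append((t.product_size, 1.0))
            continue
        if name in heteroplasmy:
            f = heteroplasmy[name]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"heteroplasmy fraction must be in [0,1], got {f}")
            fragments.extend((length, 1.0 - f) for length in t.ref_fragments)
            fragments.extend((length, f) for length in t.alt_fragments)
        else:
            geno = genotypes.get(name, "ref")
            frags = t.ref_fragments if geno == "ref" else t.alt_fragments
            fragments.extend((length, 1.0) for length in frags)
    return detect_bands(lane_from_fragments(fragments, model), model)


def observation_from_sizes(
    sizes: Sequence[float], intensities: Optional[Sequence[float]] = None
) -> LaneObservation:
    """Build a LaneObservation from plain band sizes (intensities optional)."""
    if intensities is None:
        return LaneObservation(tuple((float(s), None) for s in sizes))
    if len(intensities) != len(sizes):
        raise ValueError("sizes and intensities differ in length")
    return LaneObservation(tuple((float(s), float(i)) for s, i in zip(sizes, intensities)))


# ---------------------------------------------------------------------------
# Genotype calling

@dataclass(frozen=True)
class TargetCall:
    """Per-locus outcome: ref / alt / heteroplasmic / no_amplification /
    uncalled (the last used when the lane fails the digestion control)."""

    status: str
    fraction: Optional[float] = None  # mutant molar fraction, when estimable


@dataclass(frozen=True)
class GenotypeCall:
    """Per-lane result with evidence and internal-control status."""

    per_target: Dict[str, TargetCall]
    control_status: str   # "pass" | "fail_incomplete_digestion"
    matched: List[Tuple[float, str]] = field(default_factory=list)
    unmatched: List[float] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def _find_band(
    obs: LaneObservation, size: int, tol: int
) -> Optional[Tuple[float, Optional[float]]]:
    best = None
    for s, i in obs.bands:
        if abs(s - size) <= tol and (best is None or abs(s - size) < abs(best[0] - size)):
            best = (s, i)
    return best


def call_genotype(obs: LaneObservation, assay: AssayDefinition) -> GenotypeCall:
    """Match observed bands to the assay's expected patterns and call alleles.

    The internal-control rule is strict: any band within tolerance of a
    control-bearing target's *undigested* product size means digestion
    was incomplete, and every allele call is suppressed (``uncalled``).
    Bands below the small-band floor corroborate but are never required
    — on 2.5 % agarose the 26-31 bp fragments routinely under-stain.
    """
    if not obs.bands:
        raise ValueError("lane is empty")
    tol = assay.size_tolerance
    matched: List[Tuple[float, str]] = []
    warnings: List[str] = []
    claimed: set = set()

    # --- internal control of complete restriction
    control_status = "pass"
    for t in assay.targets:
        if not t.constant_cuts:
            continue
        hit = _find_band(obs, t.product_size, tol)
        if hit is not None:
            control_status = "fail_incomplete_digestion"
            matched.append((hit[0], f"{t.target.name}:undigested_product"))
            claimed.add(hit[0])
            warnings.append(
                f"undigested {t.product_size}-bp product present: incomplete "
                f"{assay.enzyme.name} digestion, allele calls suppressed"
            )

    per_target: Dict[str, TargetCall] = {}
    for t in assay.targets:
        name = t.target.name
        ref_hit = _find_band(obs, t.ref_principal, tol)
        alt_hit = _find_band(obs, t.alt_principal, tol)
        # corroborating small fragments
        for frags, label in ((t.ref_fragments, "ref"), (t.alt_fragments, "alt")):
            for fr in frags:
                if fr in (t.ref_principal, t.alt_principal):
                    continue
                hit = _find_band(obs, fr, tol)
                if hit is not None and hit[0] not in claimed:
                    matched.append((hit[0], f"{name}:{label}_fragment_{fr}"))
                    claimed.add(hit[0])
        if ref_hit is not None:
            matched.append((ref_hit[0], f"{name}:ref_{t.ref_principal}"))
            claimed.add(ref_hit[0])
        if alt_hit is not None:
            matched.append((alt_hit[0], f"{name}:alt_{t.alt_principal}"))
            claimed.add(alt_hit[0])
        if control_status != "pass":
            per_target[name] = TargetCall("uncalled")
            continue
        if ref_hit is None and alt_hit is None:
            per_target[name] = TargetCall("no_amplification")
        elif ref_hit is not None and alt_hit is not None:
            i_ref, i_alt = ref_hit[1], alt_hit[1]
            if i_ref is not None and i_alt is not None:
                frac = estimate_heteroplasmy(
                    i_alt, t.alt_principal, i_ref, t.ref_principal
                )
                per_target[name] = TargetCall("heteroplasmic", frac)
            else:
                per_target[name] = TargetCall("heteroplasmic", None)
        elif alt_hit is not None:
            per_target[name] = TargetCall("alt")
        else:
            per_target[name] = TargetCall("ref")

    unmatched = [s for s, _ in obs.bands if s not in claimed]
    if unmatched:
        warnings.append(f"bands matching no expected size: {sorted(unmatched)}")
    return GenotypeCall(per_target, control_status, matched, unmatched, warnings)


def estimate_heteroplasmy(
    i_cut: float, len_cut: float, i_uncut: float, len_uncut: float
) -> float:
    """Mutant molar fraction from cut/uncut band intensities.

    Under mass-proportional (ethidium-bromide) staining a band's
    intensity is molarity x length, so the molar fraction of the cut
    species is (i_cut/len_cut) / (i_cut/len_cut + i_uncut/len_uncut).
    This inverts the staining model exactly in the noise-free case.
    """
    if i_cut < 0 or i_uncut < 0:
        raise ValueError("intensities must be nonnegative")
    if len_cut <= 0 or len_uncut <= 0:
        raise ValueError("lengths must be positive")
    if i_cut == 0 and i_uncut == 0:
        raise ValueError("both intensities are zero: fraction undefined")
    m_cut = i_cut / len_cut
    m_uncut = i_uncut / len_uncut
    return m_cut / (m_cut + m_uncut)


def heteroplasmy_detection_limit(
    assay: AssayDefinition,
    target_name: str,
    model: GelModel = GelModel(),
    step: float = 0.05,
) -> float:
    """Smallest mutant fraction (on a ``step`` grid) whose diagnostic band
    is detected in an otherwise wild-type multiplex lane.

    The grid default of 5 % reflects the granularity at which mixed
    templates are usually titrated when characterizing such an assay.
    """
    t = assay.target_by_name(target_name)
    n = max(1, round(1.0 / step))
    for k in range(1, n + 1):
        f = k * step
        obs = simulate_lane(assay, {}, model, heteroplasmy={target_name: f})
        if _find_band(obs, t.alt_principal, assay.size_tolerance) is not None:
            return f
    return 1.0


# ---------------------------------------------------------------------------
# Synthetic control mixes

#: Cloned-insert regions per locus (1-based, inclusive).
CONTROL_REGIONS: Dict[str, Tuple[int, int]] = {
    "G3460A": (3275, 4272),
    "G11778A": (11580, 12118),
    "T14484C": (14449, 15022),
}

#: Mix name -> allele per locus.
CONTROL_MIXES: Dict[str, Dict[str, str]] = {
    "Normal": {"G3460A": "ref", "G11778A": "ref", "T14484C": "ref"},
    "3460A": {"G3460A": "alt", "G11778A": "ref", "T14484C": "ref"},
    "11778A": {"G3460A": "ref", "G11778A": "alt", "T14484C": "ref"},
    "14484C": {"G3460A": "ref", "G11778A": "ref", "T14484C": "alt"},
}


@dataclass(frozen=True)
class ControlMix:
    """An equimolar mix of three locus inserts, at most one mutant."""

    name: str
    inserts: Tuple[Tuple[str, NucSequence], ...]  # (allele label, insert)
    concentration_ng_per_ul: float = 1.5


def build_controls(
    ref: NucSequence,
    targets: Optional[Sequence[SnpTarget]] = None,
    regions: Optional[Dict[str, Tuple[int, int]]] = None,
) -> List[ControlMix]:
    """The four diagnostic control mixes from six cloned-insert sequences.

    Each locus contributes a wild-type and a mutant insert (bare inserts;
    no plasmid backbone is modelled) and each mix combines one insert per
    locus with at most one mutant allele.
    """
    targets = list(targets) if targets is not None else list(LHON_SNP_TARGETS)
    regions = regions or CONTROL_REGIONS
    inserts: Dict[Tuple[str, str], Tuple[str, NucSequence]] = {}
    for snp in targets:
        snp.validate_against(ref)
        start, end = regions[snp.name]
        if end > len(ref):
            raise ValueError(f"reference does not cover insert region {start}-{end}")
        for geno, allele in (("ref", snp.ref_allele), ("alt", snp.alt_allele)):
            template = ref.with_substitution(snp.position, allele)
            seq = subsequence(template, GenomicRegion(ref.id, start, end))
            label = f"{snp.position}{allele}"
            seq = NucSequence(label, seq.residues, "linear")
            inserts[(snp.name, geno)] = (label, seq)
    mixes = []
    for mix_name, assignment in CONTROL_MIXES.items():
        chosen = tuple(inserts[(t.name, assignment[t.name])] for t in targets)
        mixes.append(ControlMix(mix_name, chosen))
    return mixes


def simulate_mix_lane(
    assay: AssayDefinition, mix: ControlMix, model: GelModel = GelModel()
) -> LaneObservation:
    """Run the full assay on a control mix: PCR each insert, digest, gel."""
    fragments: List[Tuple[float, float]] = []
    for t in assay.targets:
        hits: List[Amplicon] = []
        for _, insert in mix.inserts:
            hits.extend(amplify(insert, t.fwd, t.rev))
        if len(hits) != 1:
            raise AssayConstructionError(
                f"{t.target.name}: expected one product from the mix, got {len(hits)}"
            )
        fragments.extend(
            (f.length, 1.0) for f in digest_linear(hits[0].sequence, assay.enzyme)
        )
    return detect_bands(lane_from_fragments(fragments, model), model)


# ---------------------------------------------------------------------------
# Assay documents and lane CSV I/O

def save_assay_definition(assay: AssayDefinition, path) -> None:
    doc = {
        "name": assay.name,
        "enzyme": {
            "name": assay.enzyme.name,
            "recognition": assay.enzyme.recognition,
            "cut_offset_top": assay.enzyme.cut_offset_top,
            "cut_offset_bottom": assay.enzyme.cut_offset_bottom,
        },
        "size_tolerance": assay.size_tolerance,
        "targets": [
            {
                "name": t.target.name,
                "position": t.target.position,
                "ref": t.target.ref_allele,
                "alt": t.target.alt_allele,
                "fwd": t.fwd.display(),
                "rev": t.rev.display(),
                "product_size": t.product_size,
            }
            for t in assay.targets
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_assay_definition(path=None) -> dict:
    """Read an assay document (defaults to the packaged LHON-MaeIII one)."""
    if path is None:
        refpath = resources.files("dcapsim.data").joinpath("lhon_maeiii.yaml")
        with resources.as_file(refpath) as p:
            with open(p) as fh:
                return yaml.safe_load(fh)
    with open(os.fspath(path)) as fh:
        return yaml.safe_load(fh)


def assay_from_definition(doc: dict, ref: NucSequence) -> AssayDefinition:
    """Bind a declarative assay document to a reference, with validation."""
    e = doc["enzyme"]
    enzyme = RestrictionEnzyme(
        e["name"], e["recognition"], int(e.get("cut_offset_top", 0)),
        int(e.get("cut_offset_bottom", 0)),
    )
    assay_targets = []
    for td in doc["targets"]:
        snp = SnpTarget(td["name"], int(td["position"]), td["ref"], td["alt"])
        fwd = primer_from_string(f"{td['name']}F", td["fwd"])
        rev = primer_from_string(f"{td['name']}R", td["rev"])
        t = _construct_target(ref, snp, fwd, rev, enzyme)
        declared = int(td.get("product_size", t.product_size))
        if t.product_size != declared:
            raise AssayConstructionError(
                f"{snp.name}: simulated product {t.product_size} bp != declared {declared}"
            )
        assay_targets.append(t)
    return AssayDefinition(
        name=doc.get("name", "custom"),
        enzyme=enzyme,
        targets=tuple(assay_targets),
        reference=ref,
        control_fragment=_control_fragment(assay_targets),
        size_tolerance=int(doc.get("size_tolerance", DEFAULT_SIZE_TOLERANCE)),
    )


def read_lane_csv(path) -> LaneObservation:
    """Lane CSV: one band per row, columns size[,intensity]."""
    bands = []
    with open(os.fspath(path)) as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or row[0].strip().lower() == "size":
                continue
            size = float(row[0])
            intensity = float(row[1]) if len(row) > 1 and row[1].strip() else None
            bands.append((size, intensity))
    return LaneObservation(tuple(bands))


def write_lane_csv(obs: LaneObservation, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["size", "intensity"])
        for s, i in obs.bands:
            w.writerow([f"{s:g}", "" if i is None else f"{i:g}"])
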