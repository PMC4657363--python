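# Methods

`dcapsim` models a multiplex PCR-RFLP genotyping assay end to end:
mismatch-tolerant in-silico PCR, restriction digestion with degenerate
recognition motifs, dCAPS primer design, a deterministic agarose-gel
model, and a genotype caller with an internal-digestion control. The
built-in assay is the three-locus test for the primary Leber hereditary
optic neuropathy (LHON) mitochondrial mutations m.3460G>A, m.11778G>A
and m.14484T>C, genotyped with a single enzyme (MaeIII, ↓GTnAC) after
one multiplex PCR.

## Coordinates, sequences, IUPAC semantics

All coordinates are 1-based and inclusive on the top (reference) strand,
matching mitochondrial genome convention. Origin-wrapping intervals
(`start > end`) are honoured by `subsequence` on circular sequences
only; every downstream substrate (amplicon, cloned insert) is a linear
extract, so digestion of circular sequences is rejected rather than
modelled. Residue case is preserved for display — lowercase marks
deliberate primer alterations, the convention used for dCAPS primers —
but every comparison is case-insensitive. IUPAC matching is asymmetric:
degenerate codes expand only on the motif/primer side; a degenerate base
in a template never matches (a conservative rule that avoids phantom
restriction sites in low-quality references, at the cost of missing
sites that straddle an ambiguous base).

## Restriction model

An enzyme is a recognition motif plus signed cut offsets.
`cut_offset_top` counts bases 5' of the first recognition base: 0 means
cleavage immediately before the motif (MaeIII), negative values cut
inside it (EcoRI G^AATTC is -1). Fragment sizes are defined by
**top-strand cut points only**: the assay's arithmetic (e.g.
279 + 28 + 26 = 333 for the mutant 3460 product) sums exactly to the
amplicon length only under single-strand accounting, so 5' overhangs are
not modelled. Motifs that are their own reverse complement (GTNAC is)
yield one site per footprint; non-palindromic motifs are scanned on both
strands, with the bottom-strand cut mirrored to top-strand coordinates.
Duplicate cut points from overlapping sites collapse; cuts falling at or
beyond a sequence end release nothing.

The constant MaeIII site inside the 3460 product is reported at
reference position 3736 under the convention that the position names the
**first recognition base**, with cleavage immediately 5' of it. This is
the only convention consistent with the published fragment arithmetic:
the wild-type 3460 product spans 3429–3761, and a cut between 3735 and
3736 is what yields the 307 + 26 split.

## In-silico PCR and primer override

Binding is combinatorial, not thermodynamic: a primer binds wherever its
footprint has at most `max_mismatch` (default 3) mismatches and none in
the 3'-terminal `protected_3prime` bases (default 1). Only the terminal
base is protected because dCAPS alterations legitimately occupy the
penultimate and -3/-4 positions; protecting more would reject the
built-in assay's own primers. No melting-temperature model is attempted
— the assay defines no thermodynamic parameters, and product identity,
not efficiency, is what the simulation needs.

The central convention is **primer override**: an amplicon's first
`len(fwd)` bases are the forward primer and its last `len(rev)` bases
are the reverse complement of the reverse primer, with only the interior
copied from the template. This is the mechanism by which primer
alterations implant restriction half-sites into the product: the
engineered MaeIII sites at 3460 and 14484 exist only in the PCR product,
and only when the template supplies the mutant allele immediately
downstream of the primer.

## dCAPS design search

For a SNP and an enzyme, the search enumerates every placement of the
recognition motif that overlaps the SNP, in both primer orientations.
Positions of the motif under the primer may be supplied by alterations;
positions outside it must be matched by the template carrying the
*mutant* allele, and the assembled wild-type product must not match
(discrimination). The SNP base itself is always template-provided —
altering it would destroy allele specificity. Each surviving placement
is verified by round-tripping through the PCR and digestion simulators
on both alleles; a candidate whose fragment multisets coincide is
discarded, so returned candidates carry a simulation-backed
discrimination guarantee. A placement needing zero alterations is a
natural (CAPS) design; `classify_natural_site_change` is exactly the
`max_alterations = 0` limit of the search.

Default constraints: at most 2 alterations, 3'-terminal base protected,
primer 3' end within 3 bases of the SNP, primer length 18–36. These
admit the classic dCAPS geometries (penultimate-base and -3/-4
alterations). The primer's 5' tail is copied from the template and
extended until the allele-dependent cut releases at least
`min_diagnostic_delta` bases (default 20): the released fragment equals
the shift of the principal band between genotypes, and a shift below
~20 bp would not resolve on 2.5 % agarose. This is why the published
3460 primer is a 31-mer — its length sets the 28-bp diagnostic shift.
Ties among equal-alteration candidates break toward shorter primers,
then alterations farther from the 3' terminus (extension fidelity).
Because length ranks before alteration placement, the top 14484
candidate may end `...gtC` (3'-gap 2) rather than the published
`...gtCA` (3'-gap 1); both are minimal 2-alteration designs and the
published pattern is always among the returned candidates.

Multiplex enzyme selection scores each enzyme by total alterations over
all targets, preferring enzymes with at least one natural design (ties:
more natural designs, then shorter motif), and assigns product sizes by
backtracking over a 150–500 bp ladder so that all informative bands
(≥ 50 bp) differ pairwise by at least `multiplex_min_spacing` (default
20 bp) in every genotype. Failure returns an explicit no-solution result
listing the per-enzyme reasons rather than raising.

## Gel model

Migration is affine in log size, `d = a − b·log10(bp)` with a = 10,
b = 3, detectable range 20–1500 bp — a standard empirical law; the
parameters are display-scale choices, not fits. Staining is
mass-proportional (ethidium-bromide-like): band intensity ∝ length ×
molarity, normalized within the lane, so off-gel fragments still consume
lane mass and band intensities sum to ≤ 1. Fragments migrating closer
than 0.05 units merge into one band at their mass-weighted mean size.
Detection keeps bands at ≥ 1 % of lane intensity. Products are equimolar
by default: the PCR's primer-mass asymmetry (250/60/40 ng) does not
determine product molarity, so it is carried only as optional weights.
An optional seeded multiplicative intensity noise (off by default)
supports estimator-robustness tests. ASCII rendering is deterministic —
identical inputs give identical bytes.

With these defaults the three-product wild-type lane carries total mass
307 + 26 + 164 + 236 = 733 units per molar unit, so a minor 11778-type
fraction f contributes 135·f/733 to its diagnostic band: f = 0.05 stains
at 0.92 % (below detection) and f = 0.10 at 1.84 % (above). The
heteroplasmy detection limit is therefore reported as 10 % on a 5 %
titration grid — the granularity at which mixed templates are usually
characterized for such assays.

## Genotype calling and heteroplasmy

Observed bands match expected sizes within ± 3 bp. The internal-control
rule is strict: any band within tolerance of the undigested 333-bp
product means the digest did not go to completion, and all allele calls
are suppressed (`uncalled`) — a partially digested lane would otherwise
read as wild type at every locus. Calls rest on the principal bands
(307/279, 164/135, 236/205); fragments under 50 bp corroborate but are
never required, since they under-stain and run off small-format gels.
Simultaneous cut and uncut principal bands make a target heteroplasmic;
with intensities, the mutant molar fraction is
(i_cut/L_cut) / (i_cut/L_cut + i_uncut/L_uncut), the exact inverse of
the mass-proportional staining model. Without intensities the fraction
is reported as unknown. Under 5 % multiplicative intensity noise the
estimator stays within ± 0.05 of truth for ~95 % of realizations (the
error SD peaks near 0.018 at f = 0.5).

## Synthetic references

Real reference sequence is never required. Two generators build seeded
random sequences in which primer footprints, allele-dependent sites,
constant control sites and SNP contexts are implanted at exact offsets;
every accidental occurrence of the enzyme motif — checked on the wild
type, on each single-mutant variant, and through the assembled
primer-override products — is repaired by minimal base changes, with
bounded retries on a fresh sub-seed if a conflict lands inside a
protected footprint. Construction finishes by running the real
amplify→digest pipeline per locus and genotype and asserting the exact
expected fragment sets.

* `make_lhon_like_reference` — ~3 kb, linear, locally generated
  pseudo-primers; reproduces the complete product/fragment table
  (333→307+26/279+28+26, 164→135+29, 236→205+31).
* `make_rcrs_emulation` — 16,569 bp, circular, embedding the published
  primer sequences at the genome coordinates implied by the published
  product sizes (3460 product 3429–3761, control site 3736; 11778
  product 11746–11909; 14484 product 14449–14684, anchored at the
  cloned-insert boundary 14449). It is a synthetic stand-in, not the
  real mitochondrial reference: only the primer footprints, implanted
  sites and SNP contexts are meaningful, and all filler is random.

What passing tests on these fixtures do show: the scanner, digester,
PCR, designer, gel model and caller are mutually consistent and
reproduce the assay's entire published arithmetic. What they do not
show: behaviour on real mitochondrial sequence context (off-target
primer binding on the true genome, unanticipated MaeIII sites in real
flanking sequence, NUMT-like cross-amplification), real gel artefacts,
or PCR efficiency differences between loci.

## Numerical and degenerate-input choices

Empty sequences, non-IUPAC residues and malformed table rows are
rejected with typed errors naming the offender. Zero amplicons is a
valid PCR result, not an error; an empty enzyme table is legal. Cuts
before base 1 or after the last base release nothing. Both band
intensities zero makes the heteroplasmy fraction undefined (explicit
error) rather than 0/0. Geometry generators fail with an explicit
infeasibility error when demands overlap (sites inside fixed primers,
overlapping recognition sites) instead of silently relaxing them.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely download-free:
site-scanner agreement against an independent brute-force window scan on
1,000 random sequences of 50–2,000 bp; genotype-caller round trips over
all 8 genotype vectors; heteroplasmy recovery over 200 seeded noisy
realizations per fraction; design searches and assay construction on the
16.6-kb emulation and the 3-kb fixture.

## Known limitations

No thermodynamic primer scoring, dimer or hairpin checks; designs
requiring alterations on both primers are out of scope, as are indel
targets and methylation-sensitive digestion. Partial digestion is
represented only as the caller's control-failure state, not as a
kinetic model. The gel model has no diffusion or lane distortion, so
band sizes are exact; real densitometry would add size uncertainty that
the ± 3 bp matching tolerance only partially represents.
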