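# dcapsim

In-silico design, simulation and genotype calling for multiplex PCR-RFLP
(CAPS/dCAPS) assays, built around the single-tube test for the three
primary mitochondrial mutations of Leber hereditary optic neuropathy
(LHON): m.3460G>A (ND1), m.11778G>A (ND4) and m.14484T>C (ND6).

## The problem

About 95 % of LHON cases carry one of three mitochondrial point
mutations. Each can be genotyped by restriction fragment length
polymorphism (RFLP) if an enzyme cuts one allele but not the other.
m.11778G>A naturally creates a MaeIII site (↓GTnAC). The other two
mutations do not — but because a PCR product's ends are copies of its
primers, a primer carrying one or two deliberate template mismatches
just upstream of the SNP can supply the missing bases of the motif, so
that the *mutant* product completes a MaeIII site and the wild-type
product does not (the dCAPS trick). One multiplex PCR (products of 333,
164 and 236 bp) plus one MaeIII digest then genotypes all three loci on
a single agarose lane:

| genotype | 3460 product | 11778 product | 14484 product |
|---|---|---|---|
| uncut PCR | 333 | 164 | 236 |
| wild type | 307 + 26 | 164 | 236 |
| 3460A | 279 + 28 + 26 | 164 | 236 |
| 11778A | 307 + 26 | 135 + 29 | 236 |
| 14484C | 307 + 26 | 164 | 205 + 31 |

A constant MaeIII site at reference position 3736 always splits the
3460 product (307 + 26); its 26-bp release is the internal control of
complete digestion — a lane still showing 333 bp was under-digested and
must not be genotyped. Heteroplasmy (mutant and wild-type genomes in
one sample) appears as simultaneous cut and uncut diagnostic bands;
under mass-proportional staining the mutant molar fraction is

    f = (I_cut/L_cut) / (I_cut/L_cut + I_uncut/L_uncut)

and with the default gel model the detection limit is ~10 %.

`dcapsim` implements each stage as a library module — IUPAC sequence
core, degenerate-motif restriction scanning/digestion, mismatch-tolerant
in-silico PCR with primer override, the dCAPS design search, a
deterministic gel model, and the genotype caller — plus seeded
generators of synthetic references so everything runs without any
download. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from dcapsim import builtin_lhon_assay, simulate_lane, call_genotype
from dcapsim.synthetic_fixtures import make_rcrs_emulation

ref, snps, primers = make_rcrs_emulation(seed=1)   # synthetic 16,569-bp stand-in
assay = builtin_lhon_assay(ref)                    # verifies 333/164/236 and the 26-bp control

obs = simulate_lane(assay, {"G11778A": "alt"})     # PCR -> MaeIII -> gel -> detection
print([(round(s), round(i, 3)) for s, i in obs.bands])
call = call_genotype(obs, assay)
print(call.control_status)
for name, tc in call.per_target.items():
    print(name, tc.status)
```

prints

```
[(307, 0.419), (236, 0.322), (135, 0.184), (29, 0.04), (26, 0.035)]
pass
G3460A ref
G11778A alt
T14484C ref
```

— the 11778 product was cut to 135 + 29 bp (mutant), the other two loci
show their wild-type bands, and the 26-bp control fragment confirms the
digest went to completion, so the calls are trustworthy. Band
intensities are fractions of lane mass: the 135-bp band carries
135/733 ≈ 0.18 of an equimolar lane.

The design search rediscovers the assay's primers from the reference
alone: at 3460 a single penultimate-base alteration ending `...GtC`, at
14484 two alterations ending `...gtCA`, and at 11778 a zero-alteration
(natural) design; given a panel of candidate enzymes it selects MaeIII
as the single enzyme serving all three targets.

A CLI wraps the same functions (`dcapsim amplify / digest / design /
call / gel / controls / fixtures / config-show`; exit codes 0 success,
2 usage, 3 no result, 4 control failure). `dcapsim call lane.csv` with
no `--reference` binds the bundled assay to the synthetic emulation.

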