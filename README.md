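# vrncaps

In-silico CAPS/dCAPS genotyping of the wheat vernalization gene *VRN-1*:
virtual PCR and restriction digestion over a declarative marker registry, a
decision engine that calls *VRN-A1*/*VRN-B1* alleles, infers species and
predicts growth habit, and a constraint-based synthetic-scaffold generator
that makes every assay testable without downloading a single accession.

## The problem

Whether a wheat plant needs a cold period before it will flower (winter
habit) or not (spring habit) is largely controlled by the *VRN-1* gene.
The ancestral, recessive allele confers winter habit; structural mutations
in two regulatory regions — small deletions/insertions in the promoter
around the CArG box, and large indels in intron 1 — produce dominant
spring alleles. Wild tetraploid wheat (*T. dicoccoides*, genomes BBAA)
and the diploid A-genome species (*T. monococcum*, *T. boeoticum*,
*T. urartu*) each carry their own allelic series, and several alleles are
species-diagnostic.

These alleles are routinely scored with a small panel of PCR markers:

* **CAPS** — amplify a region, digest with *Msp* I (C^CGG), read the
  fragment pattern on a gel. Example: the recessive tetraploid promoter
  amplicon (713 bp) gives bands of 200 and 138 bp; a 19 bp promoter
  deletion (*VRN-A1b*) turns 138 into a diagnostic 119 bp fragment; an
  additional 32 bp deletion (*VRN-A1d*) removes a cut site and merges two
  fragments into 147 bp; a 20 bp deletion (*VRN-A1h*) merges 162 bp with a
  neighbour into 198 bp, which co-migrates with the 200 bp band as one
  double-intensity band; a single G→C substitution 48 bp upstream of the
  start codon (*vrn-A1u*, diagnostic for *T. urartu*) creates a new site
  that splits the 162 bp fragment into 130 + 32 bp.
* **dCAPS** — for the 1 bp CArG-box deletion of *VRN-A1f*, a deliberately
  mismatched reverse primer (VRN1F_R) engineers a *Taq* I site (T^CGA)
  onto the recessive product only: the recessive 113 bp product is cut,
  the *VRN-A1f* product stays intact at 112 bp.
* **presence/absence PCR** — primer pairs flanking (or sitting inside) the
  0.5 kb intron-1 insertion (*VRN-A1ins*: 1980 vs 1476 bp), the 1.4 kb
  intron-1 deletion (1068 bp product only when the deletion is present),
  and the 7.2 kb intron-1 deletion (*VRN-A1L*: 522 bp product).

`vrncaps` reproduces this entire workflow in silico. A marker registry
declares the loci, enzymes, primer pairs, allele edit chains and the
expected product/fragment tables; synthetic promoter and intron-1
scaffolds are generated so that every placed primer footprint, every
restriction site and nothing else is present; virtual PCR (mismatch-aware
primer search with a perfect 3′ anchor, primer bases substituted into the
product) and virtual digestion then reproduce every published amplicon
and fragment length exactly, and a vector-matching caller turns observed
patterns into allele, species and growth-habit calls.

## Worked example

Genotype a synthetic *T. dicoccoides* accession carrying *VRN-A1d*:

```python
import vrncaps as v

registry = v.default_registry()
scaffolds = v.build_scaffold_set(seed=7, registry=registry)
sample = v.build_sample(registry, scaffolds, "VRN-A1d",
                        accession="IG 46277", tetraploid=True)
report = v.call_genotype(sample, registry)
print(report.a_call, report.b_call, report.species, report.habit)
for o in report.observations:
    bands = list(o.bands.bands) if o.bands is not None else None
    print(f"  {o.assay:24s} products={o.product_lengths or 'none'} bands={bands}")
```

prints

```
VRN-A1d vrn-B1 ['T. dicoccoides'] spring
  VrnA1F/Int1R             products=[662] bands=[(200, 1), (147, 1)]
  VRN1F_F/VRN1F_R          products=none bands=[]
  Indel(-)F/R              products=none bands=None
  Intr1/C/F//Intr1/AB/R    products=[1068] bands=None
  Intr1/Intr1insR          products=[1476] bands=None
  Ex1/C/F//Intr1/A/R3      products=none bands=None
  P2/P5                    products=[814] bands=[(494, 1), (128, 1), (104, 1)]
  Intr1/B/F//Intr1/B/R4    products=[1149] bands=None
```

Reading the evidence: the promoter amplicon is 662 bp (704 − 19 − 32 with
the diagnostic 147 bp merged *Msp* I fragment), the 1.4 kb intron deletion
assay amplifies (1068 bp) while its absence control does not, and the
B-genome assays show the invariant recessive *vrn-B1* (814 bp promoter
product with a 494 bp top fragment; 1149 bp intron control). The caller
resolves this vector uniquely to *VRN-A1d*, a tetraploid with a strong
spring association.

The same engine drives a CLI:

```bash
vrncaps generate --panel evaluation26 --seed 7 --out fixtures/   # 26-accession panel
vrncaps genotype --fasta fixtures/panel.fasta --out calls/ # per-sample reports
vrncaps panel --fasta fixtures/panel.fasta --roster fixtures/roster.tsv \
              --out survey/                                # survey summary
vrncaps digest --fasta fixtures/scaffolds.fasta --assay P2/P5 --gel
```

Other bundled panels: `monococcum61` (61 accessions, 19 intron-insertion
carriers → displayed frequency 31%), `boeoticum59`, `urartu40`,
`dicoccoides80` (3 accessions with the *VRN-A1b* restriction type).

## Layout

| module | role |
| --- | --- |
| `vrncaps.registry` | declarative loci/alleles/enzymes/assays; edit-chain resolution |
| `vrncaps.scaffolds` | constraint-based scaffold generator, rosters, panel builder |
| `vrncaps.pcr` | binding-site search (mismatch model) and amplicon assembly |
| `vrncaps.digest` | restriction digestion, gel-band model, text gel rendering |
| `vrncaps.caller` | panel execution, expectation matching, allele/species/habit calls |
| `vrncaps.panel` | panel genotyping, frequencies, habit contingency, concordance |
| `vrncaps.seqio` | FASTA/GFF3/TSV/JSON readers and writers |
| `vrncaps.cli` | `vrncaps` command-line tool |

See `docs/methods.md` for the model, the scaffold coordinate design, and
known limitations.
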