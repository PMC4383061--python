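# Methods

## Scope and model

`vrncaps` is a deterministic, structural model of a CAPS/dCAPS marker
panel for the wheat vernalization gene *VRN-1*. It models exactly the
quantities the wet-lab workflow reads out — amplicon lengths, restriction
fragment lengths, gel band patterns — and nothing kinetic: no primer
thermodynamics (annealing temperatures are carried as assay metadata
only), no amplification efficiency, no migration-distance physics, no
methylation sensitivity (*Msp* I is CpG-methylation-insensitive and the
templates are naked synthetic DNA), and no dimer/hairpin artifacts.

The pipeline runs in the order: registry → scaffolds → virtual PCR →
virtual digestion → gel model → genotype calling → panel summaries.

## Registry and allele model

Alleles are ordered edit chains (deletion / insertion / substitution)
relative to a parent allele, bottoming out at one of three base scaffold
contexts:

* `diploid-A` — recessive vrn-A1 of *T. monococcum* / *T. boeoticum*;
* `polyploid-A` — recessive vrn-A1u′ of *T. dicoccoides* (8 bp promoter
  insertion, the extra *Msp* I site at ATG−48, and the 1.4 kb intron-1
  deletion are all part of this baseline);
* `B` — recessive vrn-B1 (invariant in this material).

Edit anchors are stored as *(landmark, signed offset)* pairs — e.g.
`ATG−48` or `intron1_start+550` — resolved against a live landmark table
that is re-projected through every applied edit. This keeps edits valid
under scaffold regeneration and under upstream edits. Within one allele
generation, edits are applied right-to-left (descending position) so that
earlier edits cannot shift later anchors. Coordinates are 0-based,
half-open everywhere; GFF3 output converts to 1-based inclusive.

Two modelling choices in the chain structure deserve note:

* *vrn-A1u* (the *T. urartu* allele) is represented as the u′ baseline
  *minus* the 8 bp insertion (an 8 bp deletion edit). This makes the
  polyploid recessive state the chain root, so the *VRN-A1b* and
  *VRN-A1d* deltas are −19 and −51 bp relative to their own scaffold, as
  their product sizes (694/662 vs 713 bp) require. The urartu-diagnostic
  G→C substitution at ATG−48 exists additionally as a standalone named
  edit in `registry.diagnostic_edits`, applicable to the diploid scaffold
  (where it splits the 162 bp fragment into 130 + 32 bp).
* *VRN-A1f* is registered with parent *VRN-A1ins*, because in the
  surveyed material the 1 bp CArG-box deletion always co-occurs with the
  intron-1 insertion. An f-type dCAPS signal *without* the insertion is
  still representable (apply the f edit alone) and the caller reports it
  as `unattested-combination` instead of a clean call.
* *VRN-A1a* (foldback-element promoter insertion, expected dual products
  876/965 bp) is a registry stub with expected sizes only — it was found
  in none of the modelled material, and its internal structure is out of
  scope. It participates in expectation matching but can never be
  generated.

The registry serializes to JSON; `serialize → parse → serialize` is
byte-identical, and `load_registry` raises a validation error naming the
offending record (unknown parent, missing mandatory allele, fragment
table not summing to the product length, primer shorter than 15 nt, ...).

## Scaffold design

Scaffolds are synthesized, not downloaded. Each context spec pins the
features assays depend on and fills the rest with seeded random sequence
at 45% GC (a typical value for these regions; no attempt is made to
reproduce real base composition beyond that). A repair loop then
resamples filler until the sequence contains **no** occurrence of either
recognition sequence (CCGG, TCGA) and **no** binding site of any registry
primer (either strand, ≤ 2 mismatches, intact 3′ anchor) other than the
placed ones. Generation is deterministic in *(spec, seed)*; an
unsatisfiable constraint (e.g. a spurious site consisting entirely of
placed bases, or a fragment table that does not sum to its amplicon)
raises a generation error naming the violated constraint.

Promoter amplicon maps (fragment order 5′→3′; printed diagnostic sizes in
bold, filler completions chosen < 100 bp so they never create bands):

| context | amplicon | *Msp* I fragments |
| --- | --- | --- |
| diploid-A | 704 | 90, **200**, 56, **162**, **119**, 77 |
| polyploid-A | 713 | 95, **200**, 60, **138**, 32, 90, 98 |
| B (P2/P5) | 814 | **494**, **104**, **128**, 88 |

The edits are placed so that the published band arithmetic is exact:
the 19 bp *VRN-A1b* deletion sits wholly inside the 138 bp fragment
(→ 119); the 32 bp *VRN-A1d* deletion spans the site between the 60 bp
neighbour and the 119 bp fragment (60 + 119 − 32 = **147**); the 20 bp
*VRN-A1h* deletion spans the site between the 56 bp neighbour and the
162 bp fragment (56 + 162 − 20 = **198**, co-migrating with 200); the
G→C at ATG−48 completes a CCGG inside the 162 bp fragment
(→ **130** + 32). The sub-100 bp neighbours (56, 60, 32 bp) are the
minimal completions consistent with the printed bands, not measured
values.

Intron-1 scaffolds are 8,000 bp in both A contexts. The diploid layout
carries both primers of the 1.4 kb-deletion-absence assay (product
1025 bp) and the deletion-flanking pair 2,468 bp apart — beyond the
amplification cutoff, so the flanking assay is silent exactly as
observed. The polyploid layout is generated with the 1.4 kb region
already absent: the flanking pair is 1,068 bp apart and the inner reverse
primer footprint does not exist. The 7.2 kb *VRN-A1L* deletion
(`intron1_start+410`, length 7200) removes the flanking-assay footprints
and the insertion-assay reverse footprint but retains the exon-1 forward
primer and the distal reverse primer, leaving the diagnostic 522 bp
product. The 0.5 kb insertion is fixed at 504 bp (forced by the printed
1980 − 1476); 1.4 kb and 7.2 kb are nominal at 1400/7200 bp.

The dCAPS geometry: the VRN1F_F/VRN1F_R block sits inside the 162 bp
fragment of the diploid promoter. The *Taq* I site of the recessive
product spans the reverse-primer junction — template `T,C` immediately
5′ of the footprint plus the `G,A` contributed by the substituted primer.
The 1 bp *VRN-A1f* deletion removes that template `C` (the last base of
the CArG-box motif), shifting the junction so no site forms; its product
is 112 bp and stays intact, while the recessive 113 bp product is cut
into 91 + 22 bp. The published deliberate primer mismatch is modelled
exactly: the template keeps a `T` opposite primer position 2, so the
reverse primer binds with exactly one non-anchor mismatch. (With this
21-mer, no TCGA can fall wholly inside the substituted primer region, so
the junction placement is the only geometry consistent with the printed
behaviour; the site is therefore present on the raw recessive template
too, and primer substitution matters for product sequence semantics
rather than for creating the site.)

One template record is produced per genome — the promoter scaffold
concatenated with the intron-1 scaffold — so diploid accessions have one
record and tetraploids two (A and B). This is a simplified locus model
(the two regions are not spliced into a single continuous gene
structure); it is safe because no assay's primer pair spans the junction.

## Virtual PCR

Binding sites are found on both strands by vectorized IUPAC-bitmask
comparison over all windows (held to a position-by-position brute-force
oracle in the tests). Defaults: `max_mismatch = 2` and `anchor_len = 3`
(perfect 3′ clamp) — loose enough to admit the deliberate single mismatch
of VRN1F_R, strict enough that cross-genome priming is structurally
impossible on the generated scaffolds. One amplicon is emitted per
convergent site pair within the assay's `max_product` cutoff, set at
1.5× the largest expected product. The cutoff is what silences
deletion-flanking assays on non-deleted templates; the mechanism (size
cutoff vs. missing site) is not observable in the published gels, and the
cutoff is the reading this package adopts. Primer sequences are
substituted into the product verbatim, so products always begin with the
forward primer and end with the reverse complement of the reverse primer.

## Digestion and gel model

Digestion is exact: all recognition-site occurrences on the forward
strand (both enzymes are palindromic), cut offset applied, fragments
partitioning the product (conservation is asserted property-style across
the whole allele × assay matrix). The gel model drops fragments below the
**100 bp** resolvability threshold (the published gels annotate only
fragments above 100 bp) and chain-merges sizes differing by at most the
**4 bp** co-migration tolerance into one band at the largest size with
summed intensity. 4 bp is the unique small integer that superimposes
198/200 into one double-intensity band while keeping 119/130 ("double
band of about 120–130 bp") and 138/147 as separate bands.

## Genotype calling

For each assay the caller aggregates products over all templates of a
sample, digests where the assay has an enzyme, and grades the observation
against every registry allele's expected vector: `exact`, `compatible`
(product lengths within ±max(4 bp, 5%) and band sizes within the
co-migration tolerance at equal intensities), or `mismatch`. An allele is
called only if it is the *unique* allele compatible with **every**
assay; multiple survivors yield a candidate set, zero yield `unresolved`
with nearest-miss diagnostics, and disjoint exact support for different
alleles raises a `contradictory-evidence` flag. The A and B loci are
matched independently over their own assay subsets, mirroring the
genome-specificity of the wet-lab panel; tetraploid samples are unphased
template mixtures.

Note on tolerances: the ±5% length tolerance alone cannot separate
e.g. 694 from 713 bp; the discrimination in such pairs rests on the
*Msp* I band patterns (119 vs 138 bp), which the caller always consults
for enzyme assays. Since virtual sizes are exact, the tolerances only
matter for externally supplied (measured) inputs.

Species inference and habit prediction are rule layers over the call, not
statistics (the per-allele sample sizes in the habit material are 2–5):
*VRN-A1f*/*VRN-A1ins* → *T. monococcum*; *VRN-A1h* → *T. boeoticum*;
*vrn-A1u* without a B genome → *T. urartu*; the u′ lineage or any
*VRN-B1* product → *T. dicoccoides*; recessive diploid vrn-A1 → the
ambiguous {*T. monococcum*, *T. boeoticum*} set. Habit: *VRN-A1d*,
*VRN-A1L*, *VRN-A1ins*, *VRN-A1f* → spring (strong); *VRN-A1b* → winter
(weak — no spring association in this material); *VRN-A1h* → variable
(carriers split 2:2); recessive alleles → winter with an explicit caveat,
since spring accessions with fully recessive *VRN-1* exist and are listed
individually in panel concordance output rather than folded into a rate.

## Panels and survey arithmetic

Bundled rosters reproduce the published survey composition: the
26-accession habit-evaluation set; 61 *T. monococcum* (19 insertion
carriers, 4 of them *VRN-A1f*); 59 *T. boeoticum* (20 *VRN-A1h*); 40
*T. urartu* (all vrn-A1u); 80 *T. dicoccoides* (3 *VRN-A1b*, 2 *VRN-A1d*,
3 *VRN-A1L*, 72 u′). Accessions not individually named in the source
material carry `SYN-` identifiers and are synthetic roster entries that
reproduce the published counts; their habit labels are `unknown` and are
excluded from contingency tables. Percentages are displayed rounded
half-up to integers (19/61 → 31%).

`build_panel` adds background substitutions at rate 10⁻³ per base,
seeded per accession, strictly outside every assay footprint (primer
sites and amplicon spans, with a 4 bp margin) — emulating the small
inter-accession variation seen outside conserved regions without ever
disturbing a call. Panel-noise robustness across seeds is asserted in the
tests.

## What the synthetic data does and does not show

Passing tests demonstrate that the assay *design* — the coordinate
arithmetic of edits, sites and primers, and the decision rules — is
internally consistent and reproduces every published size and count
end-to-end. They do not validate performance on real sequences: real
templates contain polymorphism inside assay footprints, partial digests,
gel-estimation error (published "~140" vs exact 138), and alleles outside
the registry. Two known fidelity limits: the synthetic *T. urartu*
pattern shows a single 130 bp major band rather than the published
119 + 130 double band (a consequence of fixing the tetraploid map as
{200, 138, sub-100 filler} with no 119 bp fragment, which the *VRN-A1b*
"119 in place of 138" arithmetic requires); and the dCAPS junction site
exists on the raw recessive template, as discussed above. Problem sizes
throughout (scaffolds of ~9 kb, panels of 26–80 accessions) are the
package's chosen desk scale; a full run of every bundled panel completes
in seconds.
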