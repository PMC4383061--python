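"""Virtual PCR: site search vs brute force, amplicon semantics, symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_binding_sites

from vrncaps import (
    Template, amplify, build_sample, find_binding_sites, resolve_allele_sequence,
    revcomp,
)

DNA = st.text(alphabet="ACGT", min_size=60, max_size=400)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_empty_template_gives_empty_list():
    assert find_binding_sites("", "ACGTACGTACGTACGTACGT") == []
    assert find_binding_sites("ACGT", "ACGTACGTACGTACGTACGT") == []


def test_planted_primers_recovered_exactly_once(registry, scaffolds):
    """Every forward primer placed by the generator yields one perfect site."""
    from vrncaps.scaffolds import SCAFFOLD_SPECS

    for ctx, template in scaffolds.items():
        for p in SCAFFOLD_SPECS[ctx].placements:
            if p.kind != "primer_fwd":
                continue
            sites = find_binding_sites(template, p.seq)
            mine = [s for s in sites if s.start == p.start and s.strand == "+"]
            assert len(mine) == 1 and mine[0].mismatches == 0, (ctx, p.name)


def test_vrn1f_r_binds_with_single_engineered_mismatch(registry, scaffolds):
    """The dCAPS reverse primer carries one deliberate mismatch at position 2."""
    template = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    sites = find_binding_sites(template, registry.assay("VRN1F_F/VRN1F_R").reverse)
    assert len(sites) == 1
    (site,) = sites
    assert site.strand == "-"
    assert site.mismatches == 1
    assert site.mismatch_positions == (1,)  # 0-based: the primer's 2nd base


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6), tol=st.integers(0, 2))
def test_site_search_equals_bruteforce_oracle(seed, tol):
    """Indexed search == position-by-position oracle on random templates."""
    rng = np.random.default_rng(seed)
    template = _random_dna(rng, 1000)
    # embed a mutated copy of a template-derived 20-mer so hits actually occur
    primer = template[500:520]
    k = rng.integers(0, 3)
    pos = rng.choice(20, size=k, replace=False)
    plist = list(primer)
    for p in pos:
        plist[p] = rng.choice([b for b in "ACGT" if b != plist[p]])
    primer = "".join(plist)
    got = [(s.strand, s.start, s.mismatches)
           for s in find_binding_sites(template, primer, tol, 3)]
    assert got == brute_binding_sites(template, primer, tol, 3)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(template=DNA)
def test_iupac_primer_matches_base_sets(template):
    """Degenerate primer positions (N, R/Y) count as matches, not mismatches."""
    primer = list(template[20:40])
    primer[0] = "N"
    primer[10] = "R" if primer[10] in "AG" else "Y"
    sites = find_binding_sites(template, "".join(primer), 0, 3)
    assert any(s.start == 20 and s.strand == "+" and s.mismatches == 0
               for s in sites)


def test_amplify_uprime_promoter_single_713(registry, scaffolds):
    template = resolve_allele_sequence(registry, "vrn-A1u'", scaffolds)
    products = amplify(template, registry.assay("VrnA1F/Int1R"))
    assert [a.length for a in products] == [713]


def test_amplify_no_product_when_deletion_absent(registry, scaffolds):
    """The 1.4 kb-deletion assay stays silent on intact diploid intron 1."""
    template = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    assert amplify(template, registry.assay("Intr1/C/F//Intr1/AB/R")) == []


def test_insertion_lengthens_product_by_504(registry, scaffolds):
    assay = registry.assay("Intr1/Intr1insR")
    with_ins = amplify(resolve_allele_sequence(registry, "VRN-A1ins", scaffolds), assay)
    without = amplify(resolve_allele_sequence(registry, "vrn-A1", scaffolds), assay)
    assert with_ins[0].length - without[0].length == 504


def test_amplicon_ends_are_primer_verbatim(registry, scaffolds):
    assay = registry.assay("VrnA1F/Int1R")
    template = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    (amp,) = amplify(template, assay)
    assert amp.seq.startswith(assay.forward)
    assert amp.seq.endswith(revcomp(assay.reverse))
    assert amp.length == amp.end - amp.start == len(amp.seq)


def test_primer_substitution_overwrites_template_mismatch(registry, scaffolds):
    """The engineered dCAPS mismatch base is replaced by the primer base."""
    assay = registry.assay("VRN1F_F/VRN1F_R")
    template = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    (amp,) = amplify(template, assay)
    # template keeps the original T opposite primer position 2
    assert template.seq[amp.end - 2] == "T"
    assert amp.seq[-2] == revcomp(assay.reverse)[-2]  # primer base substituted


def test_strand_symmetry(registry, scaffolds):
    """Amplifying the reverse-complemented template yields the same products."""
    assay = registry.assay("VrnA1F/Int1R")
    for allele in ("vrn-A1", "vrn-A1u'"):
        template = resolve_allele_sequence(registry, allele, scaffolds)
        flipped = Template(id=template.id, seq=revcomp(template.seq))
        fwd = sorted(a.seq for a in amplify(template, assay))
        rev = sorted(a.seq for a in amplify(flipped, assay))
        assert fwd == rev


def test_internal_deletion_shortens_product_exactly(registry, scaffolds):
    from vrncaps import apply_edits
    from vrncaps.registry import SequenceEdit

    assay = registry.assay("VrnA1F/Int1R")
    base = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    for d in (1, 7, 33):
        edited = apply_edits(base, [SequenceEdit(
            kind="deletion", anchor_landmark="ATG", anchor_offset=-300, length=d)])
        (amp,) = amplify(edited, assay)
        assert amp.length == 704 - d


def test_max_product_cutoff_enforced(registry, scaffolds):
    """Dropping the cutoff below the product length suppresses amplification."""
    assay = registry.assay("VrnA1F/Int1R").model_copy(update={"max_product": 700})
    template = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    assert amplify(template, assay) == []


def test_cross_genome_silence(registry, scaffolds):
    """A-genome promoter primers never amplify the B template, and vice versa."""
    b = resolve_allele_sequence(registry, "vrn-B1", scaffolds)
    a = resolve_allele_sequence(registry, "vrn-A1u'", scaffolds)
    assert amplify(b, registry.assay("VrnA1F/Int1R")) == []
    assert amplify(a, registry.assay("P2/P5")) == []
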