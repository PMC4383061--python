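"""Genotype calling: panel execution, matching, decision rules, robustness."""

import numpy as np
import pytest

from vrncaps import (
    CallerParams, ObservedResult, Template, apply_edits, build_panel,
    build_sample, call_genotype, genotype_panel, match_pattern,
    resolve_allele_sequence, run_panel, habit_evaluation_roster,
)
from vrncaps.registry import SequenceEdit
from vrncaps.scaffolds import COMPATIBLE_SETTINGS


def _obs(assay, lengths, fragments=(), bands=None):
    from vrncaps.digest import to_band_pattern

    has_enzyme = assay.enzyme is not None
    band_pattern = to_band_pattern(fragments) if has_enzyme else None
    return ObservedResult(assay.name, sorted(lengths), sorted(fragments),
                          band_pattern)


def test_run_panel_rejects_empty_sample(registry):
    with pytest.raises(ValueError, match="empty sample"):
        run_panel([], registry)


def test_run_panel_tetraploid_sees_both_genomes(registry, scaffolds):
    """A VRN-A1b/vrn-B1 tetraploid yields 694 on the A assay, 814 on P2/P5."""
    sample = build_sample(registry, scaffolds, "VRN-A1b", tetraploid=True)
    obs = {o.assay: o for o in run_panel(sample, registry)}
    assert obs["VrnA1F/Int1R"].product_lengths == [694]
    assert obs["P2/P5"].product_lengths == [814]
    assert obs["Intr1/B/F//Intr1/B/R4"].product_lengths == [1149]


def test_run_panel_urartu_signature(registry, scaffolds):
    """T. urartu: no Indel(-) product; the deletion-flanking assay amplifies."""
    sample = build_sample(registry, scaffolds, "vrn-A1u")
    obs = {o.assay: o for o in run_panel(sample, registry)}
    assert obs["Indel(-)F/R"].no_product
    assert obs["Intr1/C/F//Intr1/AB/R"].product_lengths == [1068]


def test_match_grades(registry):
    assay = registry.assay("Intr1/C/F//Intr1/AB/R")
    assert match_pattern(_obs(assay, [1068]), assay, "vrn-A1u") == "exact"
    assert match_pattern(_obs(assay, []), assay, "vrn-A1") == "exact"  # both empty
    assert match_pattern(_obs(assay, [1068]), assay, "vrn-A1") == "mismatch"
    # within the +-max(4, 5%) length tolerance
    assert match_pattern(_obs(assay, [1070]), assay, "vrn-A1u") == "compatible"
    assert match_pattern(_obs(assay, [1368]), assay, "vrn-A1u") == "mismatch"


def test_length_compatible_but_band_mismatch_discriminates(registry):
    """694 vs 713 is inside the 5% length tolerance; the 119-vs-138 Msp I
    bands (Δ19 > 4 bp co-migration) still separate VRN-A1b from vrn-A1u'."""
    assay = registry.assay("VrnA1F/Int1R")
    b_obs = _obs(assay, [694], fragments=[95, 200, 60, 119, 32, 90, 98])
    assert match_pattern(b_obs, assay, "VRN-A1b") == "exact"
    assert match_pattern(b_obs, assay, "vrn-A1u'") == "mismatch"


@pytest.mark.parametrize("allele", sorted(COMPATIBLE_SETTINGS))
def test_roundtrip_identifiability(registry, scaffolds, allele):
    """generate -> genotype recovers each allele uniquely, in each context."""
    for species, tetra in COMPATIBLE_SETTINGS[allele]:
        sample = build_sample(registry, scaffolds, allele, tetraploid=tetra)
        report = call_genotype(sample, registry)
        assert report.a_call == allele, (allele, species, report.rationale)
        assert report.a_candidates == [allele]
        assert report.b_call == ("vrn-B1" if tetra else "absent")
        assert not report.flags


def test_call_vrn_a1d_tetraploid(registry, scaffolds):
    report = call_genotype(
        build_sample(registry, scaffolds, "VRN-A1d", tetraploid=True), registry)
    assert report.a_call == "VRN-A1d"
    assert report.species == ["T. dicoccoides"]
    assert (report.habit, report.habit_confidence) == ("spring", "strong")


def test_call_vrn_a1l_from_intron_signature(registry, scaffolds):
    """No product on the deletion-flanking assay plus the 522 bp product."""
    sample = build_sample(registry, scaffolds, "VRN-A1L", tetraploid=True)
    obs = {o.assay: o for o in run_panel(sample, registry)}
    assert obs["Intr1/C/F//Intr1/AB/R"].no_product
    assert obs["Ex1/C/F//Intr1/A/R3"].product_lengths == [522]
    report = call_genotype(sample, registry)
    assert report.a_call == "VRN-A1L"
    assert report.habit == "spring"


def test_species_inference_rules(registry, scaffolds):
    expected = {
        "VRN-A1f": ["T. monococcum"],
        "VRN-A1ins": ["T. monococcum"],
        "VRN-A1h": ["T. boeoticum"],
        "vrn-A1u": ["T. urartu"],
        "vrn-A1": ["T. monococcum", "T. boeoticum"],  # ambiguous by design
        "vrn-A1u'": ["T. dicoccoides"],
    }
    for allele, species in expected.items():
        tetra = allele == "vrn-A1u'"
        report = call_genotype(
            build_sample(registry, scaffolds, allele, tetraploid=tetra), registry)
        assert report.species == species, allele


def test_habit_rules(registry, scaffolds):
    expected = {
        "VRN-A1ins": ("spring", "strong"),
        "VRN-A1d": ("spring", "strong"),
        "VRN-A1b": ("winter", "weak"),
        "VRN-A1h": ("variable", "variable"),
        "vrn-A1u": ("winter", "caveat"),
        "vrn-A1": ("winter", "caveat"),
    }
    for allele, (habit, conf) in expected.items():
        tetra = allele in ("VRN-A1b", "VRN-A1d")
        report = call_genotype(
            build_sample(registry, scaffolds, allele, tetraploid=tetra), registry)
        assert (report.habit, report.habit_confidence) == (habit, conf), allele


def test_all_assays_empty_is_unresolved_with_flag(registry):
    rng = np.random.default_rng(0)
    junk = Template(id="junk|A", seq="".join(rng.choice(list("ACGT"), size=1000)))
    report = call_genotype([junk], registry)
    assert report.a_call == "unresolved"
    assert "unresolved-a-call" in report.flags
    assert report.b_call == "absent"
    assert "nearest" in report.rationale


def test_contradictory_chimera_is_flagged_not_called(registry, scaffolds):
    """A VRN-A1f promoter combined with the 1.4 kb intron deletion (attested
    in no species) must be flagged, never silently called."""
    f_template = resolve_allele_sequence(registry, "VRN-A1f", scaffolds)
    chimera = apply_edits(f_template, [SequenceEdit(
        kind="deletion", anchor_landmark="intron1_start", anchor_offset=2350,
        length=1400)])
    report = call_genotype([chimera], registry)
    assert report.a_call == "unresolved"
    assert "contradictory-evidence" in report.flags


def test_f_without_ins_flagged_unattested(registry, scaffolds):
    """The combination-free VRN-A1f signal is reported as unattested."""
    base = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    f_only = apply_edits(base, registry.allele("VRN-A1f").edits)
    report = call_genotype([f_only], registry)
    assert report.a_call == "unresolved"
    assert "unattested-combination:VRN-A1f-without-VRN-A1ins" in report.flags


@pytest.mark.parametrize("seed", [2, 3])
def test_noise_robustness_evaluation_panel(registry, scaffolds, seed):
    """Background substitutions outside assay footprints never change calls."""
    roster = habit_evaluation_roster()
    templates, truth = build_panel(roster, registry, seed=seed,
                                   scaffolds=scaffolds, noise_rate=1e-3)
    table, _ = genotype_panel(templates, registry)
    merged = table.merge(truth, on="accession")
    assert (merged["a_call"] == merged["allele"]).all()
    assert (merged.loc[merged["b_allele"] == "vrn-B1", "b_call"] == "vrn-B1").all()
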