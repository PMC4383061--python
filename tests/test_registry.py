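"""Registry data model: loading, edit chains, resolution, round-trips."""

import json

import pytest

from vrncaps import (
    RegistryError, apply_edits, default_registry, edit_delta, load_registry,
    resolve_allele_sequence,
)
from vrncaps.registry import (
    MANDATORY_ALLELES, AlleleDefinition, SequenceEdit, apply_edit,
    resolve_edit_position,
)


def test_default_registry_contents(registry):
    assert {a.name for a in registry.alleles} >= MANDATORY_ALLELES
    assert len(registry.alleles) >= 11
    assert {e.name for e in registry.enzymes} == {"MspI", "TaqI"}
    assert {s.name for s in registry.assays} == {
        "VrnA1F/Int1R", "VRN1F_F/VRN1F_R", "Indel(-)F/R",
        "Intr1/C/F//Intr1/AB/R", "Intr1/Intr1insR", "Ex1/C/F//Intr1/A/R3",
        "P2/P5", "Intr1/B/F//Intr1/B/R4",
    }
    # dCAPS primer pair as published
    dcaps = registry.assay("VRN1F_F/VRN1F_R")
    assert dcaps.forward == "ACAGCGGCTATGCTCCAGAC"
    assert dcaps.reverse == "GGAGGATGGCCAGGCCAAATC"
    for s in registry.assays:
        assert len(s.forward) >= 15 and len(s.reverse) >= 15


@pytest.mark.parametrize(
    "allele,delta",
    [
        ("vrn-A1", 0),       # identity chain of the recessive diploid
        ("VRN-A1b", -19),    # 19 bp promoter deletion
        ("VRN-A1d", -51),    # chained 19 + 32 bp deletions
        ("VRN-A1h", -20),
        ("vrn-A1u", -8),
        ("VRN-A1ins", 504),
        ("VRN-A1L", -7200),
    ],
)
def test_edit_delta(registry, allele, delta):
    assert edit_delta(registry, allele) == delta


def test_edit_delta_unknown_allele(registry):
    with pytest.raises(KeyError):
        edit_delta(registry, "VRN-A1z")


def test_registry_json_roundtrip(registry, tmp_path):
    """serialize -> parse -> serialize is byte-identical."""
    path = tmp_path / "registry.json"
    text = registry.to_json()
    path.write_text(text)
    reloaded = load_registry(path)
    assert reloaded.to_json() == text


def test_load_registry_missing_file(tmp_path):
    with pytest.raises(RegistryError, match="not found"):
        load_registry(tmp_path / "nope.json")


def test_load_registry_invalid_json(tmp_path):
    p = tmp_path / "broken.json"
    p.write_text("{not json")
    with pytest.raises(RegistryError, match="JSON"):
        load_registry(p)


def test_load_registry_unknown_parent_names_record(registry, tmp_path):
    data = json.loads(registry.to_json())
    data["alleles"][1]["parent"] = "no-such-allele"
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(data))
    with pytest.raises(RegistryError, match="no-such-allele"):
        load_registry(p)


def test_load_registry_empty_alleles_lists_missing(registry, tmp_path):
    data = json.loads(registry.to_json())
    data["alleles"] = []
    p = tmp_path / "empty.json"
    p.write_text(json.dumps(data))
    with pytest.raises(RegistryError, match="missing mandatory alleles"):
        load_registry(p)


def test_edit_invariants_enforced():
    with pytest.raises((RegistryError, ValueError)):
        SequenceEdit(kind="deletion", anchor_landmark="ATG", anchor_offset=0,
                     length=0)
    with pytest.raises((RegistryError, ValueError)):
        SequenceEdit(kind="insertion", anchor_landmark="ATG", anchor_offset=0,
                     length=8, payload="ACGT")  # payload != declared length


def test_resolution_length_matches_edit_delta(registry, scaffolds):
    """Conservation: len(resolve) - len(scaffold) == edit_delta, every allele."""
    for allele in registry.alleles:
        if allele.stub:
            continue
        ctx = registry.context_of(allele.name)
        resolved = resolve_allele_sequence(registry, allele.name, scaffolds)
        assert len(resolved.seq) - len(scaffolds[ctx].seq) == \
            edit_delta(registry, allele.name), allele.name


def test_empty_edit_chain_is_identity(registry, scaffolds):
    resolved = resolve_allele_sequence(registry, "vrn-A1", scaffolds)
    assert resolved.seq == scaffolds["diploid-A"].seq


def test_b_is_uprime_minus_19mer_naive_splice(registry, scaffolds):
    """VRN-A1b equals the u' scaffold with the 19-mer spliced out (string oracle)."""
    parent = scaffolds["polyploid-A"]
    b = resolve_allele_sequence(registry, "VRN-A1b", scaffolds)
    edit = registry.allele("VRN-A1b").edits[0]
    pos = parent.landmarks["ATG"] + edit.anchor_offset
    assert b.seq == parent.seq[:pos] + parent.seq[pos + 19:]
    assert len(b.seq) == len(parent.seq) - 19
    deleted = parent.seq[pos:pos + 19]
    assert deleted not in b.seq  # the deleted 19-mer is absent


def test_d_from_b_shortens_by_exactly_32(registry, scaffolds):
    b = resolve_allele_sequence(registry, "VRN-A1b", scaffolds)
    d = resolve_allele_sequence(registry, "VRN-A1d", scaffolds)
    assert len(b.seq) - len(d.seq) == 32
    # naive splicing oracle for the second deletion of the chain
    edit = registry.allele("VRN-A1d").edits[0]
    pos = b.landmarks["ATG"] + edit.anchor_offset
    assert d.seq == b.seq[:pos] + b.seq[pos + 32:]


def test_deletion_revert_restores_parent_bit_exact(registry, scaffolds):
    parent = resolve_allele_sequence(registry, "VRN-A1b", scaffolds)
    edit = registry.allele("VRN-A1d").edits[0]
    pos = resolve_edit_position(parent, edit)
    deleted = parent.seq[pos:pos + edit.length]
    child = apply_edit(parent, edit)
    restored = child.seq[:pos] + deleted + child.seq[pos:]
    assert restored == parent.seq


def test_landmarks_reproject_through_edits(registry, scaffolds):
    """An upstream insertion shifts downstream anchors by its length."""
    u_prime = scaffolds["polyploid-A"]
    ins = resolve_allele_sequence(registry, "VRN-A1ins", scaffolds)
    assert ins.landmarks["intron1_start"] == \
        scaffolds["diploid-A"].landmarks["intron1_start"]  # insertion is downstream
    L = resolve_allele_sequence(registry, "VRN-A1L", scaffolds)
    assert u_prime.landmarks["intron1_start"] == L.landmarks["intron1_start"]


def test_edit_anchor_outside_scaffold_errors(registry, scaffolds):
    bad = SequenceEdit(kind="deletion", anchor_landmark="ATG",
                       anchor_offset=10**6, length=5)
    with pytest.raises(RegistryError, match="outside"):
        apply_edits(scaffolds["diploid-A"], [bad])


def test_stub_allele_has_no_scaffold_support(registry, scaffolds):
    assert registry.allele("VRN-A1a").stub
    with pytest.raises(RegistryError, match="stub"):
        resolve_allele_sequence(registry, "VRN-A1a", scaffolds)


def test_base_allele_requires_context():
    with pytest.raises((RegistryError, ValueError)):
        AlleleDefinition(name="x", locus="VRN-A1")
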