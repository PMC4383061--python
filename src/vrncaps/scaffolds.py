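"""Constraint-based synthetic scaffolds and accession panels.

Every template this package genotypes is synthesized here. A scaffold spec
pins down, base by base, the features an assay depends on — primer
footprints, Msp I / Taq I sites, the CArG box, the ATG start codon — and
fills everything else with seeded random sequence (45% GC) that is then
*repaired* until it contains no spurious enzyme site and no spurious primer
binding site anywhere on either strand. The result: virtual PCR + digestion
of the generated scaffolds reproduces every published amplicon and fragment
length exactly, and genome specificity (A-genome primers silent on B
templates and vice versa) holds structurally.

Three scaffold contexts exist, one per recessive baseline:

* ``diploid-A``   — vrn-A1 of T. monococcum / T. boeoticum; promoter
  VrnA1F/Int1R amplicon 704 bp with Msp I map [90,200,56,162,119,77]
  (gel bands 200/162/119); intron 1 intact.
* ``polyploid-A`` — vrn-A1u' of T. dicoccoides; promoter amplicon 713 bp
  with map [95,200,60,138,32,90,98] (bands 200/138, the extra ATG−48 Msp I
  site and the 8 bp insertion already present); intron 1 carries the 1.4 kb
  deletion.
* ``B``           — vrn-B1; P2/P5 amplicon 814 bp with map [494,104,128,88];
  intron-1 control product 1149 bp.

Each context yields ONE template record (promoter region concatenated with
the intron-1 region); tetraploid accessions carry an A and a B record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pcr
from .registry import Registry, resolve_allele_sequence
from .sequtils import Feature, Template, merge_intervals, revcomp

__all__ = [
    "Placement", "AssayTarget", "ScaffoldSpec", "GenerationError",
    "SCAFFOLD_SPECS", "generate_scaffold", "build_scaffold_set",
    "validate_scaffold", "ValidationReport",
    "RosterRow", "roster_allele", "build_sample", "build_panel",
    "habit_evaluation_roster", "monococcum_survey_roster", "boeoticum_survey_roster",
    "urartu_survey_roster", "dicoccoides_survey_roster",
    "TETRAPLOID_SPECIES", "COMPATIBLE_SETTINGS",
]


class GenerationError(RuntimeError):
    """Scaffold constraint set unsatisfiable (or spec internally inconsistent)."""


@dataclass(frozen=True)
class Placement:
    """A literal motif stamped at a fixed scaffold position."""

    name: str
    start: int
    seq: str
    kind: str  # primer_fwd | primer_rev | enzyme_site | motif

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class AssayTarget:
    """Expected virtual-assay outcome on the base scaffold of a context."""

    assay: str
    products: tuple[int, ...]  # () means "no product"
    fragments: tuple[int, ...] | None = None


@dataclass
class ScaffoldSpec:
    name: str  # context name
    length: int
    placements: list[Placement]
    landmarks: dict[str, int]
    targets: list[AssayTarget]
    gc: float = 0.45

    def check_consistent(self) -> None:
        for p in self.placements:
            if not 0 <= p.start <= p.end <= self.length:
                raise GenerationError(
                    f"spec {self.name}: placement {p.name} outside scaffold")
        for t in self.targets:
            if t.fragments is not None and t.products and \
                    sum(t.fragments) != sum(t.products):
                raise GenerationError(
                    f"spec {self.name}: target {t.assay} fragments "
                    f"{list(t.fragments)} do not sum to product {list(t.products)}")


# ---------------------------------------------------------------------------
# Layout tables (scaffold coordinates; derived in docs/methods.md)
# ---------------------------------------------------------------------------

from .registry import PRIMERS  # noqa: E402  (single source of primer truth)

_CARG = "CCTATTTATC"  # CArG-like box; ends in the T,C that seed the dCAPS Taq I site


def _mspi_sites(cuts_amplicon: list[int], offset: int) -> list[Placement]:
    # Msp I cuts C^CGG: a cut at c needs the site CCGG starting at c-1
    return [Placement(f"MspI_cut_{c}", offset + c - 1, "CCGG", "enzyme_site")
            for c in cuts_amplicon]


def _prom_diploid_spec() -> ScaffoldSpec:
    off = 100  # flank before the VrnA1F footprint
    placements = [
        Placement("Vrn1AF", off, PRIMERS["Vrn1AF"], "primer_fwd"),
        *_mspi_sites([90, 290, 346, 508, 627], off),
        Placement("VRN1F_F", off + 361, PRIMERS["VRN1F_F"], "primer_fwd"),
        Placement("CArG", off + 443, _CARG, "motif"),
        Placement("VRN1F_R", off + 353 + 100, revcomp(PRIMERS["VRN1F_R"]), "primer_rev"),
        # the deliberate dCAPS mismatch: the template keeps the original T
        # facing primer position 2
        Placement("VRN1F_R_mismatch", off + 472, "T", "motif"),
        # pre-substitution context of the urartu Msp I gain: the base before
        # CGGG must not be C, and the G at ATG-48 is the substitution target
        Placement("ATG-48_guard", off + 474, "A", "motif"),
        Placement("ATG-48_context", off + 475, "CGGG", "motif"),
        Placement("ATG", off + 524, "ATG", "motif"),
        Placement("Int1R", off + 684, revcomp(PRIMERS["Int1R"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="diploid-A:promoter", length=904, placements=placements,
        landmarks={"ATG": off + 524},
        targets=[
            AssayTarget("VrnA1F/Int1R", (704,), (90, 200, 56, 162, 119, 77)),
            AssayTarget("VRN1F_F/VRN1F_R", (113,), (91, 22)),
            AssayTarget("P2/P5", ()),
        ],
    )


def _prom_polyploid_spec() -> ScaffoldSpec:
    off = 100
    placements = [
        Placement("Vrn1AF", off, PRIMERS["Vrn1AF"], "primer_fwd"),
        Placement("CArG", off + 483, _CARG, "motif"),
        *_mspi_sites([95, 295, 355, 493, 525, 615], off),
        Placement("ATG", off + 541, "ATG", "motif"),
        Placement("Int1R", off + 693, revcomp(PRIMERS["Int1R"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="polyploid-A:promoter", length=905, placements=placements,
        landmarks={"ATG": off + 541},
        targets=[
            AssayTarget("VrnA1F/Int1R", (713,), (95, 200, 60, 138, 32, 90, 98)),
            AssayTarget("VRN1F_F/VRN1F_R", ()),
            AssayTarget("P2/P5", ()),
        ],
    )


def _prom_b_spec() -> ScaffoldSpec:
    off = 100
    placements = [
        Placement("P2", off, PRIMERS["P2"], "primer_fwd"),
        *_mspi_sites([494, 598, 726], off),
        Placement("P5", off + 794, revcomp(PRIMERS["P5"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="B:promoter", length=1014, placements=placements, landmarks={},
        targets=[
            AssayTarget("P2/P5", (814,), (494, 104, 128, 88)),
            AssayTarget("VrnA1F/Int1R", ()),
            AssayTarget("VRN1F_F/VRN1F_R", ()),
        ],
    )


def _intron_diploid_spec() -> ScaffoldSpec:
    placements = [
        Placement("Ex1/C/F", 100, PRIMERS["Ex1/C/F"], "primer_fwd"),
        Placement("Intr1", 200, PRIMERS["Intr1"], "primer_fwd"),
        Placement("Intr1insR", 1656, revcomp(PRIMERS["Intr1insR"]), "primer_rev"),
        Placement("Indel(-)F", 1800, PRIMERS["Indel(-)F"], "primer_fwd"),
        Placement("Intr1/C/F", 2300, PRIMERS["Intr1/C/F"], "primer_fwd"),
        Placement("Indel(-)R", 2805, revcomp(PRIMERS["Indel(-)R"]), "primer_rev"),
        Placement("Intr1/AB/R", 4748, revcomp(PRIMERS["Intr1/AB/R"]), "primer_rev"),
        Placement("Intr1/A/R3", 7798, revcomp(PRIMERS["Intr1/A/R3"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="diploid-A:intron1", length=8000, placements=placements,
        landmarks={"intron1_start": 150},
        targets=[
            AssayTarget("Intr1/Intr1insR", (1476,)),
            AssayTarget("Indel(-)F/R", (1025,)),
            # the 1.4 kb region is present: the flanking product (2468 bp)
            # exceeds the amplification cutoff
            AssayTarget("Intr1/C/F//Intr1/AB/R", ()),
            AssayTarget("Ex1/C/F//Intr1/A/R3", ()),
            AssayTarget("Intr1/B/F//Intr1/B/R4", ()),
        ],
    )


def _intron_polyploid_spec() -> ScaffoldSpec:
    placements = [
        Placement("Ex1/C/F", 100, PRIMERS["Ex1/C/F"], "primer_fwd"),
        Placement("Intr1", 200, PRIMERS["Intr1"], "primer_fwd"),
        Placement("Intr1insR", 1656, revcomp(PRIMERS["Intr1insR"]), "primer_rev"),
        # Indel(-)R fell inside the 1.4 kb deletion; its mate remains
        Placement("Indel(-)F", 1800, PRIMERS["Indel(-)F"], "primer_fwd"),
        Placement("Intr1/C/F", 2300, PRIMERS["Intr1/C/F"], "primer_fwd"),
        Placement("Intr1/AB/R", 3348, revcomp(PRIMERS["Intr1/AB/R"]), "primer_rev"),
        Placement("Intr1/A/R3", 7798, revcomp(PRIMERS["Intr1/A/R3"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="polyploid-A:intron1", length=8000, placements=placements,
        landmarks={"intron1_start": 150},
        targets=[
            AssayTarget("Intr1/Intr1insR", (1476,)),
            AssayTarget("Indel(-)F/R", ()),
            AssayTarget("Intr1/C/F//Intr1/AB/R", (1068,)),
            AssayTarget("Ex1/C/F//Intr1/A/R3", ()),
            AssayTarget("Intr1/B/F//Intr1/B/R4", ()),
        ],
    )


def _intron_b_spec() -> ScaffoldSpec:
    placements = [
        Placement("Intr1/B/F", 100, PRIMERS["Intr1/B/F"], "primer_fwd"),
        Placement("Intr1/B/R4", 1227, revcomp(PRIMERS["Intr1/B/R4"]), "primer_rev"),
    ]
    return ScaffoldSpec(
        name="B:intron1", length=1349, placements=placements, landmarks={},
        targets=[
            AssayTarget("Intr1/B/F//Intr1/B/R4", (1149,)),
            AssayTarget("Intr1/Intr1insR", ()),
            AssayTarget("Indel(-)F/R", ()),
            AssayTarget("Intr1/C/F//Intr1/AB/R", ()),
            AssayTarget("Ex1/C/F//Intr1/A/R3", ()),
        ],
    )


def _merge_specs(context: str, parts: list[ScaffoldSpec]) -> ScaffoldSpec:
    """Concatenate region specs into one template-level context spec."""
    placements: list[Placement] = []
    landmarks: dict[str, int] = {}
    targets: list[AssayTarget] = []
    seen_assays: set[str] = set()
    off = 0
    for part in parts:
        for p in part.placements:
            placements.append(Placement(p.name, p.start + off, p.seq, p.kind))
        for k, v in part.landmarks.items():
            landmarks[k] = v + off
        for t in part.targets:
            if t.assay in seen_assays:
                # keep the positive target if one region yields a product
                if t.products:
                    targets = [x for x in targets if x.assay != t.assay]
                    seen_assays.discard(t.assay)
                else:
                    continue
            targets.append(t)
            seen_assays.add(t.assay)
        off += part.length
    return ScaffoldSpec(name=context, length=off, placements=placements,
                        landmarks=landmarks, targets=targets)


SCAFFOLD_SPECS: dict[str, ScaffoldSpec] = {
    "diploid-A": _merge_specs("diploid-A", [_prom_diploid_spec(), _intron_diploid_spec()]),
    "polyploid-A": _merge_specs("polyploid-A", [_prom_polyploid_spec(), _intron_polyploid_spec()]),
    "B": _merge_specs("B", [_prom_b_spec(), _intron_b_spec()]),
}

_ENZYME_MOTIFS = ("CCGG", "TCGA")
_MAX_REPAIR_ROUNDS = 200


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _planted_mask(spec: ScaffoldSpec) -> np.ndarray:
    mask = np.zeros(spec.length, dtype=bool)
    for p in spec.placements:
        mask[p.start:p.end] = True
    return mask


def _amplicon_spans(spec: ScaffoldSpec, registry: Registry) -> list[tuple[int, int]]:
    """Footprint spans of every *productive* assay target, for protection."""
    pos = {p.name: p for p in spec.placements}
    spans: list[tuple[int, int]] = []
    for t in spec.targets:
        if not t.products:
            continue
        assay = registry.assay(t.assay)
        f = pos.get(assay.forward_name)
        r = pos.get(assay.reverse_name)
        if f is not None and r is not None:
            spans.append((f.start, r.end))
    return spans


def generate_scaffold(
    spec: ScaffoldSpec,
    seed: int,
    primers: dict[str, str] | None = None,
) -> Template:
    """Generate a scaffold satisfying every placement and exclusion constraint.

    Deterministic for a given (spec, seed). Random filler is resampled under
    a bounded repair loop until the sequence contains no enzyme recognition
    site and no primer binding site (either strand, up to the default
    mismatch tolerance) other than those placed. Raises
    :class:`GenerationError` if a constraint cannot be satisfied — e.g. a
    spurious site made entirely of placed bases, or an inconsistent spec.
    """
    spec.check_consistent()
    primers = primers if primers is not None else dict(PRIMERS)
    rng = np.random.default_rng([seed, zlib.crc32(spec.name.encode()) & 0x7FFFFFFF])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    gc_half = spec.gc / 2
    at_half = (1 - spec.gc) / 2
    p = [at_half, gc_half, gc_half, at_half]

    arr = rng.choice(bases, size=spec.length, p=p)
    for pl in spec.placements:
        arr[pl.start:pl.end] = np.frombuffer(pl.seq.encode(), dtype=np.uint8)
    planted = _planted_mask(spec)

    for _ in range(_MAX_REPAIR_ROUNDS):
        seq = arr.tobytes().decode()
        bad: list[tuple[int, int]] = []
        for motif in _ENZYME_MOTIFS:
            i = seq.find(motif)
            while i != -1:
                if not planted[i:i + len(motif)].all():
                    bad.append((i, i + len(motif)))
                i = seq.find(motif, i + 1)
        for primer in primers.values():
            for site in pcr.find_binding_sites(seq, primer):
                if not planted[site.start:site.end].all():
                    bad.append((site.start, site.end))
        if not bad:
            break
        for s, e in bad:
            free = np.arange(s, e)[~planted[s:e]]
            if free.size == 0:
                raise GenerationError(
                    f"spec {spec.name}: spurious site at [{s},{e}) consists "
                    f"entirely of placed bases — constraint set unsatisfiable")
            arr[free] = rng.choice(bases, size=free.size, p=p)
    else:
        raise GenerationError(
            f"spec {spec.name}: repair loop did not converge in "
            f"{_MAX_REPAIR_ROUNDS} rounds")

    features = [Feature(p.name, p.start, p.end, p.kind) for p in spec.placements]
    protected = merge_intervals(
        [(p.start, p.end) for p in spec.placements]
    )
    return Template(id=f"scaffold|{spec.name}", seq=arr.tobytes().decode(),
                    landmarks=dict(spec.landmarks), features=features,
                    protected=protected)


def build_scaffold_set(seed: int, registry: Registry | None = None) -> dict[str, Template]:
    """One base template per scaffold context, with assay spans protected."""
    from .registry import default_registry
    registry = registry or default_registry()
    out: dict[str, Template] = {}
    for ctx, spec in SCAFFOLD_SPECS.items():
        t = generate_scaffold(spec, seed)
        t.protected = merge_intervals(t.protected + _amplicon_spans(spec, registry))
        out[ctx] = t
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]


def validate_scaffold(
    template: Template, spec: ScaffoldSpec, registry: Registry
) -> ValidationReport:
    """Re-derive every constraint by search (not from annotations).

    Checks, in order: each placed primer binds at its intended position; each
    assay target's amplicon length and digest fragment multiset; absence of
    spurious enzyme and primer sites outside placements.
    """
    from .digest import digest as digest_product

    report = ValidationReport()
    seq = template.seq
    planted = np.zeros(len(seq), dtype=bool)
    for p in spec.placements:
        if p.end <= len(seq):
            planted[p.start:p.end] = True

    for p in spec.placements:
        if p.kind not in ("primer_fwd", "primer_rev"):
            continue
        primer = p.seq if p.kind == "primer_fwd" else revcomp(p.seq)
        sites = pcr.find_binding_sites(seq, primer)
        found = any(s.start == p.start for s in sites)
        report.checks.append(Check(f"primer:{p.name}@{p.start}", found,
                                   "" if found else "binding site not recovered"))

    for t in spec.targets:
        assay = registry.assay(t.assay)
        prods = pcr.amplify(template, assay)
        lengths = sorted(a.length for a in prods)
        want = sorted(t.products)
        ok = lengths == want
        detail = "" if ok else (
            f"expected {'no product' if not want else want}, got "
            f"{'no product' if not lengths else lengths}")
        report.checks.append(Check(f"amplicon:{t.assay}", ok, detail))
        if t.fragments is not None and assay.enzyme:
            enz = registry.enzyme(assay.enzyme)
            got = sorted(f for a in prods for f in digest_product(a, enz).fragments)
            ok = got == sorted(t.fragments)
            report.checks.append(Check(
                f"fragments:{t.assay}", ok,
                "" if ok else f"expected {sorted(t.fragments)}, got {got}"))

    spurious: list[str] = []
    for enz_name in ("CCGG", "TCGA"):
        i = seq.find(enz_name)
        while i != -1:
            if not planted[i:i + 4].all():
                spurious.append(f"{enz_name}@{i}")
            i = seq.find(enz_name, i + 1)
    report.checks.append(Check("no-spurious-enzyme-sites", not spurious,
                               ",".join(spurious)))
    stray: list[str] = []
    for name, primer in PRIMERS.items():
        for s in pcr.find_binding_sites(seq, primer):
            if not planted[s.start:s.end].all():
                stray.append(f"{name}@{s.start}{s.strand}")
    report.checks.append(Check("no-spurious-primer-sites", not stray,
                               ",".join(stray)))
    return report


# ---------------------------------------------------------------------------
# Accession rosters and panel construction
# ---------------------------------------------------------------------------

TETRAPLOID_SPECIES = {"T. dicoccoides"}

_SPECIES = {"T. monococcum", "T. boeoticum", "T. urartu", "T. dicoccoides"}


@dataclass(frozen=True)
class RosterRow:
    accession: str
    species: str
    promoter_allele: str
    intron_state: str  # intact | ins | del1.4 | del1.4+7.2
    habit: str = "unknown"  # spring | winter | unknown

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"roster {self.accession}: unknown species {self.species!r}")
        if self.habit not in ("spring", "winter", "unknown"):
            raise ValueError(f"roster {self.accession}: bad habit {self.habit!r}")


_ROSTER_ALLELE = {
    ("vrn-A1", "intact"): "vrn-A1",
    ("vrn-A1", "ins"): "VRN-A1ins",
    ("VRN-A1f", "ins"): "VRN-A1f",
    ("VRN-A1h", "intact"): "VRN-A1h",
    ("vrn-A1u", "del1.4"): "vrn-A1u",
    ("vrn-A1u'", "del1.4"): "vrn-A1u'",
    ("VRN-A1b", "del1.4"): "VRN-A1b",
    ("VRN-A1d", "del1.4"): "VRN-A1d",
    ("vrn-A1u'", "del1.4+7.2"): "VRN-A1L",
}


def roster_allele(row: RosterRow) -> str:
    """Map a roster (promoter allele, intron state) to the registry allele."""
    key = (row.promoter_allele, row.intron_state)
    if key not in _ROSTER_ALLELE:
        raise KeyError(
            f"roster row {row.accession}: combination {key} unknown to registry")
    return _ROSTER_ALLELE[key]


#: compatible (species, tetraploid) settings per registry allele, used by the
#: full round-trip identifiability matrix
COMPATIBLE_SETTINGS: dict[str, list[tuple[str, bool]]] = {
    "vrn-A1": [("T. monococcum", False), ("T. boeoticum", False)],
    "VRN-A1ins": [("T. monococcum", False)],
    "VRN-A1f": [("T. monococcum", False)],
    "VRN-A1h": [("T. boeoticum", False)],
    "vrn-A1u": [("T. urartu", False)],
    "vrn-A1u'": [("T. dicoccoides", True)],
    "VRN-A1b": [("T. dicoccoides", True)],
    "VRN-A1d": [("T. dicoccoides", True)],
    "VRN-A1L": [("T. dicoccoides", True)],
}


def habit_evaluation_roster() -> list[RosterRow]:
    """The 26-accession growth-habit evaluation set."""
    R = RosterRow
    return [
        # T. monococcum
        R("TRI 1510", "T. monococcum", "vrn-A1", "ins", "spring"),
        R("TRI 17025", "T. monococcum", "vrn-A1", "intact", "spring"),
        R("TRI 17212", "T. monococcum", "vrn-A1", "ins", "spring"),
        R("TRI 17973", "T. monococcum", "vrn-A1", "intact", "spring"),
        R("TRI 28871", "T. monococcum", "VRN-A1f", "ins", "spring"),
        # T. boeoticum
        R("TRI 17062", "T. boeoticum", "vrn-A1", "intact", "winter"),
        R("TRI 17071", "T. boeoticum", "VRN-A1h", "intact", "spring"),
        R("TRI 17072", "T. boeoticum", "vrn-A1", "intact", "spring"),
        R("TRI 17098", "T. boeoticum", "VRN-A1h", "intact", "spring"),
        R("TRI 17103", "T. boeoticum", "VRN-A1h", "intact", "winter"),
        R("TRI 17117", "T. boeoticum", "vrn-A1", "intact", "winter"),
        R("TRI 17164", "T. boeoticum", "VRN-A1h", "intact", "winter"),
        # T. urartu
        R("TRI 17174", "T. urartu", "vrn-A1u", "del1.4", "winter"),
        R("TRI 17118", "T. urartu", "vrn-A1u", "del1.4", "winter"),
        R("TRI 17121", "T. urartu", "vrn-A1u", "del1.4", "winter"),
        R("TRI 17138", "T. urartu", "vrn-A1u", "del1.4", "winter"),
        R("TRI 17141", "T. urartu", "vrn-A1u", "del1.4", "winter"),
        # T. dicoccoides
        R("IG 113301", "T. dicoccoides", "vrn-A1u'", "del1.4", "winter"),
        R("IG 46273", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        R("IG 46306", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        R("IG 115810", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        R("IG 46277", "T. dicoccoides", "VRN-A1d", "del1.4", "spring"),
        R("IG 46288", "T. dicoccoides", "VRN-A1d", "del1.4", "spring"),
        R("IG 139189", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
        R("IG 46297", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
        R("k-5198", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
    ]


def monococcum_survey_roster() -> list[RosterRow]:
    """61 T. monococcum accessions: 19 insertion carriers (4 of them VRN-A1f).

    Accessions beyond the individually named ones are synthetic roster
    entries (SYN-M*) reproducing the published carrier counts.
    """
    rows = [
        RosterRow("TRI 1510", "T. monococcum", "vrn-A1", "ins", "spring"),
        RosterRow("TRI 17212", "T. monococcum", "vrn-A1", "ins", "spring"),
        RosterRow("TRI 28871", "T. monococcum", "VRN-A1f", "ins", "spring"),
    ]
    for i in range(3):  # three further VRN-A1f carriers found by CAPS screening
        rows.append(RosterRow(f"SYN-M-F{i + 1:02d}", "T. monococcum",
                              "VRN-A1f", "ins", "spring"))
    for i in range(13):  # remaining insertion-only carriers (19 total)
        rows.append(RosterRow(f"SYN-M-I{i + 1:02d}", "T. monococcum",
                              "vrn-A1", "ins", "spring"))
    rows.append(RosterRow("TRI 17025", "T. monococcum", "vrn-A1", "intact", "spring"))
    rows.append(RosterRow("TRI 17973", "T. monococcum", "vrn-A1", "intact", "spring"))
    for i in range(40):  # remaining recessive accessions (42 total)
        rows.append(RosterRow(f"SYN-M-R{i + 1:02d}", "T. monococcum",
                              "vrn-A1", "intact", "winter"))
    assert len(rows) == 61
    return rows


def boeoticum_survey_roster() -> list[RosterRow]:
    """59 T. boeoticum accessions: 20 VRN-A1h carriers, 39 recessive."""
    rows = [
        RosterRow("TRI 17071", "T. boeoticum", "VRN-A1h", "intact", "spring"),
        RosterRow("TRI 17098", "T. boeoticum", "VRN-A1h", "intact", "spring"),
        RosterRow("TRI 17103", "T. boeoticum", "VRN-A1h", "intact", "winter"),
        RosterRow("TRI 17164", "T. boeoticum", "VRN-A1h", "intact", "winter"),
    ]
    for i in range(16):
        rows.append(RosterRow(f"SYN-B-H{i + 1:02d}", "T. boeoticum",
                              "VRN-A1h", "intact", "unknown"))
    rows += [
        RosterRow("TRI 17062", "T. boeoticum", "vrn-A1", "intact", "winter"),
        RosterRow("TRI 17072", "T. boeoticum", "vrn-A1", "intact", "spring"),
        RosterRow("TRI 17117", "T. boeoticum", "vrn-A1", "intact", "winter"),
    ]
    for i in range(36):
        rows.append(RosterRow(f"SYN-B-R{i + 1:02d}", "T. boeoticum",
                              "vrn-A1", "intact", "unknown"))
    assert len(rows) == 59
    return rows


def urartu_survey_roster() -> list[RosterRow]:
    """40 T. urartu accessions, all vrn-A1u winter types where evaluated."""
    rows = [RosterRow(a, "T. urartu", "vrn-A1u", "del1.4", "winter")
            for a in ("TRI 17174", "TRI 17118", "TRI 17121", "TRI 17138", "TRI 17141")]
    for i in range(35):
        rows.append(RosterRow(f"SYN-U-{i + 1:02d}", "T. urartu",
                              "vrn-A1u", "del1.4", "unknown"))
    return rows


def dicoccoides_survey_roster() -> list[RosterRow]:
    """80 T. dicoccoides accessions: 3 VRN-A1b, 2 VRN-A1d, 3 VRN-A1L, 72 u'."""
    rows = [
        RosterRow("IG 46273", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        RosterRow("IG 46306", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        RosterRow("IG 115810", "T. dicoccoides", "VRN-A1b", "del1.4", "winter"),
        RosterRow("IG 46277", "T. dicoccoides", "VRN-A1d", "del1.4", "spring"),
        RosterRow("IG 46288", "T. dicoccoides", "VRN-A1d", "del1.4", "spring"),
        RosterRow("IG 139189", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
        RosterRow("IG 46297", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
        RosterRow("k-5198", "T. dicoccoides", "vrn-A1u'", "del1.4+7.2", "spring"),
        RosterRow("IG 113301", "T. dicoccoides", "vrn-A1u'", "del1.4", "winter"),
    ]
    for i in range(71):
        rows.append(RosterRow(f"SYN-D-{i + 1:02d}", "T. dicoccoides",
                              "vrn-A1u'", "del1.4", "unknown"))
    assert len(rows) == 80
    return rows


ROSTERS = {
    "evaluation26": habit_evaluation_roster,
    "monococcum61": monococcum_survey_roster,
    "boeoticum59": boeoticum_survey_roster,
    "urartu40": urartu_survey_roster,
    "dicoccoides80": dicoccoides_survey_roster,
}


def _apply_noise(template: Template, rng: np.random.Generator,
                 rate: float, margin: int = 4) -> Template:
    """Seeded background substitutions outside all protected assay footprints."""
    if rate <= 0:
        return template
    prot = merge_intervals([(max(0, s - margin), min(len(template.seq), e + margin))
                            for s, e in template.protected])
    mask = np.ones(len(template.seq), dtype=bool)
    for s, e in prot:
        mask[s:e] = False
    free = np.nonzero(mask)[0]
    if free.size == 0:
        return template
    k = rng.binomial(free.size, rate)
    if k == 0:
        return template
    pos = rng.choice(free, size=k, replace=False)
    arr = np.frombuffer(template.seq.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in pos:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    t = template.copy()
    t.seq = arr.tobytes().decode()
    return t


def build_sample(
    registry: Registry,
    scaffolds: dict[str, Template],
    allele: str,
    accession: str = "sample",
    tetraploid: bool = False,
) -> list[Template]:
    """Noise-free template set for one accession carrying `allele`."""
    a = resolve_allele_sequence(registry, allele, scaffolds)
    a.id = f"{accession}|A"
    out = [a]
    if tetraploid:
        b = resolve_allele_sequence(registry, "vrn-B1", scaffolds)
        b.id = f"{accession}|B"
        out.append(b)
    return out


def build_panel(
    roster: list[RosterRow],
    registry: Registry,
    seed: int,
    scaffolds: dict[str, Template] | None = None,
    noise_rate: float = 1e-3,
) -> tuple[list[Template], pd.DataFrame]:
    """Materialize an accession panel: templates plus a truth table.

    Tetraploid accessions get two template records (A and B genome); all
    accessions receive seeded background substitutions at ``noise_rate``
    outside every assayed footprint, mimicking inter-accession variation
    without disturbing any assay.
    """
    scaffolds = scaffolds or build_scaffold_set(seed, registry)
    templates: list[Template] = []
    truth_rows = []
    for i, row in enumerate(roster):
        allele = roster_allele(row)  # raises naming the row on unknown combos
        tetra = row.species in TETRAPLOID_SPECIES
        sample = build_sample(registry, scaffolds, allele, row.accession, tetra)
        for j, t in enumerate(sample):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, 7919 * (i + 1) + j])
            templates.append(_apply_noise(t, rng, noise_rate))
        truth_rows.append({
            "accession": row.accession,
            "species": row.species,
            "allele": allele,
            "b_allele": "vrn-B1" if tetra else "",
            "promoter_allele": row.promoter_allele,
            "intron_state": row.intron_state,
            "habit": row.habit,
        })
    truth = pd.DataFrame(truth_rows,
                         columns=["accession", "species", "allele", "b_allele",
                                  "promoter_allele", "intron_state", "habit"])
    return templates, truth
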