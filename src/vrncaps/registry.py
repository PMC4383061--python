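"""Declarative marker registry for the VRN-1 CAPS/dCAPS assay system.

The registry is the single source of truth for the genotyping engine: the two
homoeologous loci (VRN-A1 on the A genome, VRN-B1 on the B genome), the
allelic series expressed as edit chains, the two restriction enzymes, and the
eight PCR marker assays with their expected product and fragment tables.

Allele model
------------
Each allele is an ordered chain of :class:`SequenceEdit` objects relative to a
parent allele, bottoming out at a base scaffold context:

* ``diploid-A`` — the recessive vrn-A1 promoter/intron-1 of einkorn-group
  diploids (T. monococcum, T. boeoticum). Derived alleles: VRN-A1ins (0.5 kb
  intron-1 insertion), VRN-A1f (1 bp CArG-box deletion, on the ins
  background), VRN-A1h (20 bp promoter deletion).
* ``polyploid-A`` — the recessive vrn-A1u' of tetraploid wheat (8 bp promoter
  insertion and the extra Msp I site at ATG−48 already present; 1.4 kb
  intron-1 deletion already present). Derived: vrn-A1u (the T. urartu state,
  i.e. u' without the 8 bp insertion), VRN-A1b (19 bp promoter deletion),
  VRN-A1d (additional 32 bp deletion spanning an Msp I site), VRN-A1L
  (7.2 kb intron-1 deletion).
* ``B`` — the recessive vrn-B1, invariant in this system.

Edit anchors are stored as (landmark, signed offset) pairs — e.g. the Msp I
site gained by T. urartu is a G→C substitution anchored at ATG−48 — so the
edits survive scaffold regeneration. Anchors are resolved against the
template's live landmark table and therefore re-project correctly through
upstream edits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .sequtils import Template, project_through, validate_dna

__all__ = [
    "RestrictionEnzyme",
    "SequenceEdit",
    "AlleleDefinition",
    "Locus",
    "MarkerAssay",
    "Registry",
    "RegistryError",
    "load_registry",
    "default_registry",
    "edit_delta",
    "resolve_allele_sequence",
    "apply_edits",
    "MANDATORY_ALLELES",
]


class RegistryError(ValueError):
    """Schema or referential-integrity violation in a registry config."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class RestrictionEnzyme(BaseModel):
    """A restriction endonuclease with a palindromic recognition site."""

    name: str
    recognition: str
    cut_offset: int

    @model_validator(mode="after")
    def _check(self) -> "RestrictionEnzyme":
        if not self.recognition:
            raise RegistryError(f"enzyme {self.name}: empty recognition sequence")
        self.recognition = validate_dna(self.recognition, name=f"enzyme {self.name}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise RegistryError(
                f"enzyme {self.name}: cut offset {self.cut_offset} outside "
                f"recognition sequence of length {len(self.recognition)}"
            )
        return self


class SequenceEdit(BaseModel):
    """One structural change, anchored to a named landmark.

    ``anchor_landmark`` + ``anchor_offset`` give the 0-based position of the
    first affected base. Deletions remove ``length`` bases; insertions insert
    ``payload`` *before* the anchor position; substitutions overwrite
    ``length`` bases with ``payload``.
    """

    kind: Literal["deletion", "insertion", "substitution"]
    anchor_landmark: str
    anchor_offset: int
    length: int
    payload: str = ""

    @model_validator(mode="after")
    def _check(self) -> "SequenceEdit":
        if self.kind == "deletion":
            if self.length <= 0:
                raise RegistryError("deletion length must be > 0")
            if self.payload:
                raise RegistryError("deletion carries no payload")
        elif self.kind == "insertion":
            if len(self.payload) != self.length:
                raise RegistryError(
                    f"insertion payload length {len(self.payload)} != declared {self.length}"
                )
        elif self.kind == "substitution":
            if len(self.payload) != self.length:
                raise RegistryError(
                    f"substitution payload length {len(self.payload)} != replaced {self.length}"
                )
        if self.payload:
            self.payload = validate_dna(self.payload, name="edit payload")
        return self

    @property
    def delta(self) -> int:
        """Signed length change caused by this edit."""
        if self.kind == "deletion":
            return -self.length
        if self.kind == "insertion":
            return self.length
        return 0


class AlleleDefinition(BaseModel):
    """A named allele as an edit chain relative to a parent allele/scaffold."""

    name: str
    locus: str
    parent: Optional[str] = None  # None => base allele of `context`
    context: Optional[str] = None  # scaffold context; required for base alleles
    edits: list[SequenceEdit] = Field(default_factory=list)
    dominance: Literal["dominant-spring", "recessive", "weak", "variable"] = "recessive"
    species_specificity: list[str] = Field(default_factory=list)
    stub: bool = False  # expected sizes only, no scaffold support (VRN-A1a)

    @model_validator(mode="after")
    def _check(self) -> "AlleleDefinition":
        if self.parent is None and self.context is None and not self.stub:
            raise RegistryError(f"allele {self.name}: base allele needs a context")
        return self


class Locus(BaseModel):
    """A VRN-1 locus with its assayed regions mapped to scaffold contexts."""

    name: Literal["VRN-A1", "VRN-B1"]
    genome: Literal["A", "B"]
    regions: dict[str, list[str]]  # region name -> scaffold contexts carrying it

    @model_validator(mode="after")
    def _check(self) -> "Locus":
        if len(set(self.regions)) != len(self.regions):
            raise RegistryError(f"locus {self.name}: duplicate region names")
        return self


class MarkerAssay(BaseModel):
    """A primer pair, optional enzyme, and the expected result table.

    ``expected_products`` maps allele name to a list of product lengths (an
    empty list means "no product"); ``expected_fragments`` maps allele name to
    the restriction-fragment multiset of the product for enzyme assays.
    ``max_product`` is the amplification length cutoff (the virtual analogue
    of extension-time limits): site pairs further apart yield no product.
    """

    name: str
    locus: str
    forward_name: str
    forward: str
    reverse_name: str
    reverse: str
    enzyme: Optional[str] = None
    expected_products: dict[str, list[int]] = Field(default_factory=dict)
    expected_fragments: dict[str, list[int]] = Field(default_factory=dict)
    max_product: int = 0
    annealing_c: float = 0.0  # metadata only

    @field_validator("forward", "reverse")
    @classmethod
    def _primer_ok(cls, v: str) -> str:
        v = validate_dna(v, name="primer")
        if len(v) < 15:
            raise RegistryError(f"primer {v!r} shorter than 15 bases")
        return v

    @model_validator(mode="after")
    def _check(self) -> "MarkerAssay":
        for allele, frags in self.expected_fragments.items():
            prods = self.expected_products.get(allele)
            if prods and sum(frags) != sum(prods):
                raise RegistryError(
                    f"assay {self.name}, allele {allele}: fragments {frags} do not "
                    f"sum to product length {prods}"
                )
        return self


class Registry(BaseModel):
    """Validated collection of loci, enzymes, alleles and assays."""

    loci: list[Locus]
    enzymes: list[RestrictionEnzyme]
    alleles: list[AlleleDefinition]
    assays: list[MarkerAssay]
    diagnostic_edits: dict[str, SequenceEdit] = Field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    def allele(self, name: str) -> AlleleDefinition:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(f"unknown allele {name!r}")

    def enzyme(self, name: str) -> RestrictionEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(f"unknown enzyme {name!r}")

    def assay(self, name: str) -> MarkerAssay:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(f"unknown assay {name!r}")

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"unknown locus {name!r}")

    def assays_for_locus(self, locus: str) -> list[MarkerAssay]:
        return [a for a in self.assays if a.locus == locus]

    def alleles_for_locus(self, locus: str) -> list[AlleleDefinition]:
        return [a for a in self.alleles if a.locus == locus]

    def chain(self, name: str) -> list[AlleleDefinition]:
        """Allele chain from base scaffold to `name` (base first)."""
        chain: list[AlleleDefinition] = []
        cur: Optional[str] = name
        seen: set[str] = set()
        while cur is not None:
            if cur in seen:
                raise RegistryError(f"allele {name}: cyclic parent chain at {cur}")
            seen.add(cur)
            a = self.allele(cur)
            chain.append(a)
            cur = a.parent
        return list(reversed(chain))

    def context_of(self, name: str) -> str:
        base = self.chain(name)[0]
        if base.context is None:
            raise RegistryError(f"allele {name}: no scaffold context (stub?)")
        return base.context

    # -- validation ---------------------------------------------------------
    @model_validator(mode="after")
    def _referential_integrity(self) -> "Registry":
        allele_names = {a.name for a in self.alleles}
        if len(allele_names) != len(self.alleles):
            raise RegistryError("duplicate allele names")
        missing = MANDATORY_ALLELES - allele_names
        if missing:
            raise RegistryError(f"missing mandatory alleles: {sorted(missing)}")
        enzyme_names = {e.name for e in self.enzymes}
        locus_names = {l.name for l in self.loci}
        for a in self.alleles:
            if a.parent is not None and a.parent not in allele_names:
                raise RegistryError(f"allele {a.name}: unknown parent {a.parent!r}")
            if a.locus not in locus_names:
                raise RegistryError(f"allele {a.name}: unknown locus {a.locus!r}")
            self.chain(a.name)  # raises on cycles
        for s in self.assays:
            if s.enzyme is not None and s.enzyme not in enzyme_names:
                raise RegistryError(f"assay {s.name}: unknown enzyme {s.enzyme!r}")
            if s.locus not in locus_names:
                raise RegistryError(f"assay {s.name}: unknown locus {s.locus!r}")
            for al in list(s.expected_products) + list(s.expected_fragments):
                if al not in allele_names:
                    raise RegistryError(f"assay {s.name}: expected-product allele {al!r} not in registry")
        return self

    def to_json(self, indent: int = 2) -> str:
        return self.model_dump_json(indent=indent)


def load_registry(path: str | Path) -> Registry:
    """Load and validate a registry config from JSON.

    Raises :class:`RegistryError` naming the offending record on schema or
    referential-integrity violations.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry config not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return Registry.model_validate(data)
    except RegistryError:
        raise
    except Exception as exc:  # pydantic ValidationError
        raise RegistryError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Edit application
# ---------------------------------------------------------------------------

def resolve_edit_position(template: Template, edit: SequenceEdit) -> int:
    """Resolve an edit anchor against the template's landmark table."""
    if edit.anchor_landmark not in template.landmarks:
        raise RegistryError(
            f"edit anchor landmark {edit.anchor_landmark!r} not on template {template.id}"
        )
    pos = template.landmarks[edit.anchor_landmark] + edit.anchor_offset
    if not 0 <= pos <= len(template.seq):
        raise RegistryError(
            f"edit anchor {edit.anchor_landmark}{edit.anchor_offset:+d} falls outside "
            f"template {template.id} (position {pos}, length {len(template.seq)})"
        )
    return pos


def apply_edit(template: Template, edit: SequenceEdit) -> Template:
    """Apply a single edit, returning a new template with landmarks re-projected."""
    pos = resolve_edit_position(template, edit)
    t = template.copy()
    if edit.kind == "deletion":
        if pos + edit.length > len(t.seq):
            raise RegistryError(
                f"deletion at {pos}+{edit.length} overruns template {t.id}"
            )
        t.seq = t.seq[:pos] + t.seq[pos + edit.length:]
        project_through(t, pos, -edit.length)
    elif edit.kind == "insertion":
        t.seq = t.seq[:pos] + edit.payload + t.seq[pos:]
        project_through(t, pos, edit.length)
    else:  # substitution
        if pos + edit.length > len(t.seq):
            raise RegistryError(f"substitution at {pos} overruns template {t.id}")
        t.seq = t.seq[:pos] + edit.payload + t.seq[pos + edit.length:]
    return t


def apply_edits(template: Template, edits: Iterable[SequenceEdit]) -> Template:
    """Apply one generation of edits in coordinate-stable (right-to-left) order."""
    edits = list(edits)
    order = sorted(
        range(len(edits)),
        key=lambda i: resolve_edit_position(template, edits[i]),
        reverse=True,
    )
    t = template
    for i in order:
        t = apply_edit(t, edits[i])
    return t


def edit_delta(registry: Registry, allele: str) -> int:
    """Cumulative signed length change of the full edit chain vs the base scaffold."""
    return sum(e.delta for a in registry.chain(allele) for e in a.edits)


def resolve_allele_sequence(
    registry: Registry, allele: str, scaffolds: dict[str, Template]
) -> Template:
    """Materialize an allele by applying its edit chain, parent-first.

    ``scaffolds`` maps scaffold context names to base templates (see
    :mod:`vrncaps.scaffolds`). Edits within one generation are applied
    right-to-left so earlier edits do not shift later anchors; landmarks are
    re-projected through every edit, so anchors of later generations resolve
    against the already-edited sequence.
    """
    chain = registry.chain(allele)
    base = chain[0]
    if base.stub:
        raise RegistryError(f"allele {allele}: stub without scaffold support")
    ctx = base.context
    if ctx not in scaffolds:
        raise RegistryError(f"allele {allele}: base scaffold context {ctx!r} missing")
    t = scaffolds[ctx].copy()
    for gen in chain:
        t = apply_edits(t, gen.edits)
    t.id = f"{t.id}|{allele}"
    return t


# ---------------------------------------------------------------------------
# Bundled default registry
# ---------------------------------------------------------------------------

MANDATORY_ALLELES = {
    "vrn-A1", "vrn-A1u", "vrn-A1u'", "VRN-A1b", "VRN-A1d", "VRN-A1f",
    "VRN-A1h", "VRN-A1ins", "VRN-A1L", "vrn-B1", "VRN-A1a",
}

PRIMERS: dict[str, str] = {
    "Vrn1AF": "GAAAGGAAAAATTCTGCTCG",
    "Int1R": "GCAGGAAATCGAAATCGAAG",
    "VRN1F_F": "ACAGCGGCTATGCTCCAGAC",
    "VRN1F_R": "GGAGGATGGCCAGGCCAAATC",
    "Indel(-)F": "CGCTCTTATATTTGTTTACCAGGG",
    "Indel(-)R": "GGGTCAACTATTCTGTGGAG",
    "Intr1/C/F": "GCACTCCTAACCCACTAACC",
    "Intr1/AB/R": "TCATCCATCATCAAGGCAAA",
    "Intr1": "ATCATCTTCTCCACCAAGGG",
    "Intr1insR": "AATGAACAGCACGGAAACAG",
    "Ex1/C/F": "GTTCTCCACCGAGTCATGGT",
    "Intr1/A/R3": "AAGTAAGACAACACGAATGTGAGA",
    "P2": "TCATGCACGCACACACGGTA",
    "P5": "GGCCAACCCTACACCCCAAG",
    "Intr1/B/F": "CAAGTGGAACGGTTAGGACA",
    "Intr1/B/R4": "CAAATGAAAAGGAATGAGAGCA",
}

#: deterministic 504 bp payload of the VRN-A1ins intron-1 insertion
_INS_PAYLOAD_SEED = 20150331
_INS_PAYLOAD_LEN = 504


def _ins_payload() -> str:
    rng = np.random.default_rng(_INS_PAYLOAD_SEED)
    bases = np.array(list("ACGT"))
    p = [0.275, 0.225, 0.225, 0.275]  # 45% GC
    while True:
        s = "".join(rng.choice(bases, size=_INS_PAYLOAD_LEN, p=p))
        if "CCGG" not in s and "TCGA" not in s:
            return s


def _edit(kind: str, landmark: str, offset: int, length: int, payload: str = "") -> SequenceEdit:
    return SequenceEdit(
        kind=kind, anchor_landmark=landmark, anchor_offset=offset,
        length=length, payload=payload,
    )


def default_registry() -> Registry:
    """The bundled registry encoding the full marker table and allelic series."""
    mspi = RestrictionEnzyme(name="MspI", recognition="CCGG", cut_offset=1)
    taqi = RestrictionEnzyme(name="TaqI", recognition="TCGA", cut_offset=1)

    loci = [
        Locus(name="VRN-A1", genome="A",
              regions={"promoter": ["diploid-A", "polyploid-A"],
                       "intron1": ["diploid-A", "polyploid-A"]}),
        Locus(name="VRN-B1", genome="B",
              regions={"promoter": ["B"], "intron1": ["B"]}),
    ]

    alleles = [
        # --- diploid-A lineage (T. monococcum / T. boeoticum) ---
        AlleleDefinition(name="vrn-A1", locus="VRN-A1", context="diploid-A",
                         dominance="recessive"),
        AlleleDefinition(name="VRN-A1ins", locus="VRN-A1", parent="vrn-A1",
                         edits=[_edit("insertion", "intron1_start", 550,
                                      _INS_PAYLOAD_LEN, _ins_payload())],
                         dominance="dominant-spring",
                         species_specificity=["T. monococcum"]),
        # VRN-A1f is only attested in combination with VRN-A1ins
        AlleleDefinition(name="VRN-A1f", locus="VRN-A1", parent="VRN-A1ins",
                         edits=[_edit("deletion", "ATG", -72, 1)],
                         dominance="dominant-spring",
                         species_specificity=["T. monococcum"]),
        AlleleDefinition(name="VRN-A1h", locus="VRN-A1", parent="vrn-A1",
                         edits=[_edit("deletion", "ATG", -188, 20)],
                         dominance="variable",
                         species_specificity=["T. boeoticum"]),
        # --- polyploid-A lineage (T. urartu / T. dicoccoides) ---
        AlleleDefinition(name="vrn-A1u'", locus="VRN-A1", context="polyploid-A",
                         dominance="recessive"),
        # T. urartu: the u' state minus the 8 bp insertion
        AlleleDefinition(name="vrn-A1u", locus="VRN-A1", parent="vrn-A1u'",
                         edits=[_edit("deletion", "ATG", -86, 8)],
                         dominance="recessive",
                         species_specificity=["T. urartu"]),
        AlleleDefinition(name="VRN-A1b", locus="VRN-A1", parent="vrn-A1u'",
                         edits=[_edit("deletion", "ATG", -141, 19)],
                         dominance="weak"),
        AlleleDefinition(name="VRN-A1d", locus="VRN-A1", parent="VRN-A1b",
                         edits=[_edit("deletion", "ATG", -177, 32)],
                         dominance="dominant-spring"),
        AlleleDefinition(name="VRN-A1L", locus="VRN-A1", parent="vrn-A1u'",
                         edits=[_edit("deletion", "intron1_start", 410, 7200)],
                         dominance="dominant-spring"),
        # foldback-element promoter insertion: registry stub, no scaffold
        AlleleDefinition(name="VRN-A1a", locus="VRN-A1", stub=True,
                         dominance="dominant-spring"),
        # --- B genome ---
        AlleleDefinition(name="vrn-B1", locus="VRN-B1", context="B",
                         dominance="recessive"),
    ]

    # shorthand fragment maps of the VrnA1F/Int1R Msp I digest
    frags_dipl = [90, 200, 56, 162, 119, 77]           # recessive diploid, 704 bp
    frags_dipl_f = [90, 200, 56, 161, 119, 77]         # 1 bp CArG deletion, 703 bp
    frags_dipl_h = [90, 200, 198, 119, 77]             # 20 bp deletion merges 56+162
    frags_poly = [95, 200, 60, 138, 32, 90, 98]        # recessive tetraploid, 713 bp
    frags_poly_u = [95, 200, 60, 130, 32, 90, 98]      # minus the 8 bp insertion
    frags_poly_b = [95, 200, 60, 119, 32, 90, 98]      # 19 bp deletion: 138 -> 119
    frags_poly_d = [95, 200, 147, 32, 90, 98]          # 32 bp deletion merges 60+119

    assays = [
        MarkerAssay(
            name="VrnA1F/Int1R", locus="VRN-A1",
            forward_name="Vrn1AF", forward=PRIMERS["Vrn1AF"],
            reverse_name="Int1R", reverse=PRIMERS["Int1R"],
            enzyme="MspI", annealing_c=55.0, max_product=1448,
            expected_products={
                "vrn-A1": [704], "VRN-A1ins": [704], "VRN-A1f": [703],
                "VRN-A1h": [684], "vrn-A1u": [705], "vrn-A1u'": [713],
                "VRN-A1b": [694], "VRN-A1d": [662], "VRN-A1L": [713],
                "VRN-A1a": [876, 965], "vrn-B1": [],
            },
            expected_fragments={
                "vrn-A1": frags_dipl, "VRN-A1ins": frags_dipl,
                "VRN-A1f": frags_dipl_f, "VRN-A1h": frags_dipl_h,
                "vrn-A1u": frags_poly_u, "vrn-A1u'": frags_poly,
                "VRN-A1b": frags_poly_b, "VRN-A1d": frags_poly_d,
                "VRN-A1L": frags_poly,
            },
        ),
        MarkerAssay(
            name="VRN1F_F/VRN1F_R", locus="VRN-A1",
            forward_name="VRN1F_F", forward=PRIMERS["VRN1F_F"],
            reverse_name="VRN1F_R", reverse=PRIMERS["VRN1F_R"],
            enzyme="TaqI", annealing_c=58.0, max_product=170,
            expected_products={
                "vrn-A1": [113], "VRN-A1ins": [113], "VRN-A1f": [112],
                "VRN-A1h": [113], "vrn-A1u": [], "vrn-A1u'": [],
                "VRN-A1b": [], "VRN-A1d": [], "VRN-A1L": [], "vrn-B1": [],
            },
            expected_fragments={
                "vrn-A1": [91, 22], "VRN-A1ins": [91, 22],
                "VRN-A1f": [112], "VRN-A1h": [91, 22],
            },
        ),
        MarkerAssay(
            name="Indel(-)F/R", locus="VRN-A1",
            forward_name="Indel(-)F", forward=PRIMERS["Indel(-)F"],
            reverse_name="Indel(-)R", reverse=PRIMERS["Indel(-)R"],
            annealing_c=50.0, max_product=1538,
            expected_products={
                "vrn-A1": [1025], "VRN-A1ins": [1025], "VRN-A1f": [1025],
                "VRN-A1h": [1025], "vrn-A1u": [], "vrn-A1u'": [],
                "VRN-A1b": [], "VRN-A1d": [], "VRN-A1L": [], "vrn-B1": [],
            },
        ),
        MarkerAssay(
            name="Intr1/C/F//Intr1/AB/R", locus="VRN-A1",
            forward_name="Intr1/C/F", forward=PRIMERS["Intr1/C/F"],
            reverse_name="Intr1/AB/R", reverse=PRIMERS["Intr1/AB/R"],
            annealing_c=56.0, max_product=1602,
            expected_products={
                "vrn-A1": [], "VRN-A1ins": [], "VRN-A1f": [], "VRN-A1h": [],
                "vrn-A1u": [1068], "vrn-A1u'": [1068], "VRN-A1b": [1068],
                "VRN-A1d": [1068], "VRN-A1L": [], "vrn-B1": [],
            },
        ),
        MarkerAssay(
            name="Intr1/Intr1insR", locus="VRN-A1",
            forward_name="Intr1", forward=PRIMERS["Intr1"],
            reverse_name="Intr1insR", reverse=PRIMERS["Intr1insR"],
            annealing_c=50.0, max_product=2970,
            expected_products={
                "vrn-A1": [1476], "VRN-A1ins": [1980], "VRN-A1f": [1980],
                "VRN-A1h": [1476], "vrn-A1u": [1476], "vrn-A1u'": [1476],
                "VRN-A1b": [1476], "VRN-A1d": [1476], "VRN-A1L": [],
                "vrn-B1": [],
            },
        ),
        MarkerAssay(
            name="Ex1/C/F//Intr1/A/R3", locus="VRN-A1",
            forward_name="Ex1/C/F", forward=PRIMERS["Ex1/C/F"],
            reverse_name="Intr1/A/R3", reverse=PRIMERS["Intr1/A/R3"],
            annealing_c=55.6, max_product=783,
            expected_products={
                "vrn-A1": [], "VRN-A1ins": [], "VRN-A1f": [], "VRN-A1h": [],
                "vrn-A1u": [], "vrn-A1u'": [], "VRN-A1b": [], "VRN-A1d": [],
                "VRN-A1L": [522], "vrn-B1": [],
            },
        ),
        MarkerAssay(
            name="P2/P5", locus="VRN-B1",
            forward_name="P2", forward=PRIMERS["P2"],
            reverse_name="P5", reverse=PRIMERS["P5"],
            enzyme="MspI", annealing_c=55.0, max_product=1221,
            expected_products={"vrn-B1": [814]},
            expected_fragments={"vrn-B1": [494, 104, 128, 88]},
        ),
        MarkerAssay(
            name="Intr1/B/F//Intr1/B/R4", locus="VRN-B1",
            forward_name="Intr1/B/F", forward=PRIMERS["Intr1/B/F"],
            reverse_name="Intr1/B/R4", reverse=PRIMERS["Intr1/B/R4"],
            annealing_c=56.4, max_product=1724,
            expected_products={"vrn-B1": [1149]},
        ),
    ]

    diagnostic_edits = {
        # T. urartu-diagnostic Msp I site gain (splits the 162 bp fragment 130+32
        # when applied to the diploid recessive promoter)
        "mspI_gain_G_to_C_at_ATG-48": _edit("substitution", "ATG", -48, 1, "C"),
        # unwired micro-variant seen in one spring T. boeoticum accession
        # (TRI 17072): T->C plus a 1 bp deletion ~200 bp into intron 1
        "intron1_T_to_C_plus_1bp_del": _edit("substitution", "intron1_start", 200, 1, "C"),
        "intron1_1bp_del_at_201": _edit("deletion", "intron1_start", 201, 1),
    }

    return Registry(
        loci=loci, enzymes=[mspi, taqi], alleles=alleles, assays=assays,
        diagnostic_edits=diagnostic_edits,
    )
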