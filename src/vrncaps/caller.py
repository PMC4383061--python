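"""Genotype calling: run the assay panel, match expectations, call alleles.

The caller executes all eight marker assays on a sample (one template for
diploids, two — A and B genome — for tetraploids), then matches the observed
product lengths and gel band patterns against the registry's expected-result
table. Allele calls are *vector-matched*: the called allele is the unique
registry allele whose full expected-result vector is compatible with every
observation, so a single noisy assay degrades the call to a candidate set or
an "unresolved" report with nearest-miss diagnostics instead of producing a
wrong definitive call.

On top of the allele call sit two rule layers distilled from the survey
data: species inference (VRN-A1f/VRN-A1ins are diagnostic for
T. monococcum, VRN-A1h for T. boeoticum, vrn-A1u for T. urartu, the u'
lineage and any VRN-B1 product for polyploid wheat) and growth-habit
prediction (intron-1 structural alleles and VRN-A1d confer spring habit;
VRN-A1b shows no spring association; VRN-A1h is variable; the recessive
allele predicts winter with documented spring exceptions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from . import pcr
from .digest import BandPattern, GelModel, digest as digest_product, to_band_pattern
from .pcr import PCRParams
from .registry import MarkerAssay, Registry
from .sequtils import Template

__all__ = [
    "MatchParams", "CallerParams", "ObservedResult", "GenotypeReport",
    "run_panel", "match_pattern", "call_genotype", "infer_species",
    "predict_habit",
]


@dataclass(frozen=True)
class MatchParams:
    """Product-length tolerance: ±max(min_tol, rel_tol·size) bp."""

    rel_tol: float = 0.05
    min_tol: int = 4

    def tol(self, size: int) -> int:
        return max(self.min_tol, round(self.rel_tol * size))


@dataclass(frozen=True)
class CallerParams:
    pcr: PCRParams = field(default_factory=PCRParams)
    gel: GelModel = field(default_factory=GelModel)
    match: MatchParams = field(default_factory=MatchParams)


@dataclass
class ObservedResult:
    """Aggregated outcome of one assay over all templates of a sample."""

    assay: str
    product_lengths: list[int]
    fragments: list[int]  # combined over products; empty for non-enzyme assays
    bands: BandPattern | None  # present iff the assay has an enzyme

    @property
    def no_product(self) -> bool:
        return not self.product_lengths


@dataclass
class GenotypeReport:
    """Per-sample genotyping outcome with evidence and rationale."""

    sample: str
    a_call: str  # allele name, "candidates:<a|b>", or "unresolved"
    a_candidates: list[str]
    b_call: str  # "vrn-B1", "absent", or "unresolved"
    evidence: dict[str, dict[str, str]]  # allele -> assay -> match grade
    species: list[str]
    habit: str  # spring | winter | variable | unknown
    habit_confidence: str  # strong | weak | variable | caveat | n/a
    rationale: str
    flags: list[str]
    observations: list[ObservedResult] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "sample": self.sample,
            "a_call": self.a_call,
            "a_candidates": self.a_candidates,
            "b_call": self.b_call,
            "species": self.species,
            "habit": self.habit,
            "habit_confidence": self.habit_confidence,
            "rationale": self.rationale,
            "flags": self.flags,
            "observations": [
                {
                    "assay": o.assay,
                    "products": o.product_lengths,
                    "fragments": o.fragments,
                    "bands": list(o.bands.bands) if o.bands is not None else None,
                }
                for o in self.observations
            ],
            "evidence": self.evidence,
        }


# ---------------------------------------------------------------------------
# Panel execution
# ---------------------------------------------------------------------------

def run_panel(
    sample: list[Template],
    registry: Registry,
    params: CallerParams | None = None,
) -> list[ObservedResult]:
    """Run every registry assay on every template of a sample.

    Tetraploid samples present both genome templates to every assay; products
    are aggregated per assay, exactly as a PCR on pooled genomic DNA would.
    """
    if not sample:
        raise ValueError("empty sample: at least one template required")
    params = params or CallerParams()
    results: list[ObservedResult] = []
    for assay in registry.assays:
        products = [a for t in sample for a in pcr.amplify(t, assay, params.pcr)]
        lengths = sorted(a.length for a in products)
        fragments: list[int] = []
        bands: BandPattern | None = None
        if assay.enzyme is not None:
            enz = registry.enzyme(assay.enzyme)
            fragments = sorted(f for a in products
                               for f in digest_product(a, enz).fragments)
            bands = to_band_pattern(fragments, params.gel)
        results.append(ObservedResult(assay.name, lengths, fragments, bands))
    return results


# ---------------------------------------------------------------------------
# Expectation matching
# ---------------------------------------------------------------------------

def _match_lengths(observed: list[int], expected: list[int], mp: MatchParams) -> str:
    if len(observed) != len(expected):
        return "mismatch"
    if not expected:
        return "exact"  # no product expected, none seen
    grade = "exact"
    for o, e in zip(sorted(observed), sorted(expected)):
        if o == e:
            continue
        if abs(o - e) <= mp.tol(e):
            grade = "compatible"
        else:
            return "mismatch"
    return grade


def _expected_bands(assay: MarkerAssay, allele: str, gel: GelModel) -> BandPattern | None:
    frags = assay.expected_fragments.get(allele)
    if frags is None:
        return BandPattern(bands=()) if not assay.expected_products.get(allele) else None
    return to_band_pattern(frags, gel)


def _match_bands(observed: BandPattern, expected: BandPattern, gel: GelModel) -> str:
    if len(observed.bands) != len(expected.bands):
        return "mismatch"
    grade = "exact"
    for (os_, oi), (es, ei) in zip(observed.bands, expected.bands):
        if oi != ei:
            return "mismatch"
        if os_ == es:
            continue
        if abs(os_ - es) <= gel.comigration_tol:
            grade = "compatible"
        else:
            return "mismatch"
    return grade


_GRADE_ORDER = {"exact": 0, "compatible": 1, "mismatch": 2}


def match_pattern(
    observed: ObservedResult,
    assay: MarkerAssay,
    allele: str,
    params: CallerParams | None = None,
) -> str:
    """Grade one observation against one allele's expectation.

    Returns ``exact`` (lengths and bands identical), ``compatible`` (within
    the size tolerance / co-migration tolerance), or ``mismatch``.
    """
    params = params or CallerParams()
    expected = assay.expected_products.get(allele, [])
    grade = _match_lengths(observed.product_lengths, list(expected), params.match)
    if grade == "mismatch":
        return grade
    if assay.enzyme is not None and observed.bands is not None:
        exp_bands = _expected_bands(assay, allele, params.gel)
        if exp_bands is not None:
            bgrade = _match_bands(observed.bands, exp_bands, params.gel)
            grade = max(grade, bgrade, key=lambda g: _GRADE_ORDER[g])
    return grade


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _match_locus(
    observations: dict[str, ObservedResult],
    registry: Registry,
    locus: str,
    params: CallerParams,
) -> tuple[list[str], dict[str, dict[str, str]]]:
    """Alleles of `locus` whose full expected vector matches all observations."""
    assays = registry.assays_for_locus(locus)
    evidence: dict[str, dict[str, str]] = {}
    full: list[str] = []
    for allele in registry.alleles_for_locus(locus):
        grades = {
            a.name: match_pattern(observations[a.name], a, allele.name, params)
            for a in assays
        }
        evidence[allele.name] = grades
        if all(g != "mismatch" for g in grades.values()):
            full.append(allele.name)
    return full, evidence


def _nearest_miss(evidence: dict[str, dict[str, str]]) -> str:
    scored = sorted(
        (
            (sum(1 for g in grades.values() if g != "mismatch"), name, grades)
            for name, grades in evidence.items()
        ),
        key=lambda x: (-x[0], x[1]),
    )
    best_n, name, grades = scored[0]
    bad = [a for a, g in grades.items() if g == "mismatch"]
    return f"nearest {name} ({best_n}/{len(grades)} assays; mismatched: {', '.join(bad)})"


def infer_species(report: GenotypeReport, registry: Registry) -> list[str]:
    """Species candidate set implied by the allele call and B-locus state."""
    call = report.a_call
    b_present = report.b_call == "vrn-B1"
    if call in ("VRN-A1f", "VRN-A1ins"):
        return ["T. monococcum"]
    if call == "VRN-A1h":
        return ["T. boeoticum"]
    if call == "vrn-A1u" and not b_present:
        return ["T. urartu"]
    if b_present or call in ("vrn-A1u'", "VRN-A1b", "VRN-A1d", "VRN-A1L"):
        return ["T. dicoccoides"]
    if call == "vrn-A1":
        return ["T. monococcum", "T. boeoticum"]
    return []


_HABIT_RULES: dict[str, tuple[str, str, str]] = {
    # allele -> (habit, confidence, rationale)
    "VRN-A1d": ("spring", "strong", "promoter deletion series reaching the CArG box"),
    "VRN-A1L": ("spring", "strong", "large intron-1 deletion allele"),
    "VRN-A1ins": ("spring", "strong", "0.5 kb intron-1 insertion allele"),
    "VRN-A1f": ("spring", "strong", "1 bp CArG-box deletion (with intron-1 insertion)"),
    "VRN-A1b": ("winter", "weak", "19 bp promoter deletion shows no spring association"),
    "VRN-A1h": ("variable", "variable", "carriers split between spring and winter"),
    "vrn-A1": ("winter", "caveat",
               "recessive allele; spring exceptions attested in surveyed accessions"),
    "vrn-A1u": ("winter", "caveat", "recessive T. urartu allele; all carriers winter"),
    "vrn-A1u'": ("winter", "caveat", "recessive tetraploid allele"),
    "vrn-B1": ("winter", "caveat", "recessive B-genome allele"),
    "VRN-A1a": ("spring", "strong", "foldback-element promoter insertion (stub)"),
}


def predict_habit(report: GenotypeReport, registry: Registry) -> tuple[str, str, str]:
    """Rule-based growth-habit prediction from the A-locus call."""
    call = report.a_call
    if call in _HABIT_RULES:
        return _HABIT_RULES[call]
    return ("unknown", "n/a", "no resolved A-locus allele")


def call_genotype(
    sample: list[Template],
    registry: Registry,
    params: CallerParams | None = None,
) -> GenotypeReport:
    """Full decision chain: panel -> allele vectors -> species -> habit."""
    params = params or CallerParams()
    observations = run_panel(sample, registry, params)
    by_assay = {o.assay: o for o in observations}
    sample_id = sample[0].id.split("|")[0]

    a_full, a_evidence = _match_locus(by_assay, registry, "VRN-A1", params)
    flags: list[str] = []

    if len(a_full) == 1:
        a_call = a_full[0]
    elif len(a_full) > 1:
        a_call = "candidates:" + "|".join(sorted(a_full))
        flags.append("ambiguous-a-call")
    else:
        a_call = "unresolved"
        flags.append("unresolved-a-call")
        # contradiction: disjoint assays each exactly supporting different alleles
        exact_support = {
            name for name, grades in a_evidence.items()
            if any(g == "exact" for g in grades.values())
            and any(g == "mismatch" for g in grades.values())
        }
        if len(exact_support) >= 2:
            flags.append("contradictory-evidence")
        # VRN-A1f promoter signal without the intron-1 insertion is unattested
        f_grades = a_evidence.get("VRN-A1f", {})
        if (f_grades.get("VRN1F_F/VRN1F_R") == "exact"
                and f_grades.get("Intr1/Intr1insR") == "mismatch"):
            flags.append("unattested-combination:VRN-A1f-without-VRN-A1ins")

    # B locus, called independently; "absent" when no B assay yields a product
    b_full, b_evidence = _match_locus(by_assay, registry, "VRN-B1", params)
    b_assays = registry.assays_for_locus("VRN-B1")
    if all(by_assay[a.name].no_product for a in b_assays):
        b_call = "absent"
    elif b_full:
        b_call = b_full[0]
    else:
        b_call = "unresolved"
        flags.append("unresolved-b-call")

    report = GenotypeReport(
        sample=sample_id,
        a_call=a_call,
        a_candidates=sorted(a_full),
        b_call=b_call,
        evidence={**a_evidence, **b_evidence},
        species=[],
        habit="unknown",
        habit_confidence="n/a",
        rationale="",
        flags=flags,
        observations=observations,
    )
    report.species = infer_species(report, registry)
    habit, conf, why = predict_habit(report, registry)
    report.habit, report.habit_confidence = habit, conf
    report.rationale = _nearest_miss(a_evidence) if a_call == "unresolved" else why
    return report
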