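"""Panel-scale orchestration: genotype whole accession panels and summarize.

Reproduces the survey arithmetic of the marker study: per-species allele
counts and frequencies, allele × growth-habit contingency tables, and
predicted-vs-observed habit concordance with exceptions listed by accession
(the survey discusses its exceptions individually, so the summary does the
same rather than collapsing them into a single rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import groupby
from typing import Any

import pandas as pd

from .caller import CallerParams, GenotypeReport, call_genotype
from .registry import Registry
from .scaffolds import RosterRow
from .sequtils import Template

__all__ = ["PanelSummary", "genotype_panel", "summarize", "habit_association",
           "display_percent"]


def display_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to an integer for display (19/61 -> 31)."""
    if denominator == 0:
        return 0
    pct = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class PanelSummary:
    """Aggregate survey statistics for a genotyped panel."""

    panel_size: int
    species_counts: dict[str, int]
    allele_counts: dict[str, dict[str, int]]  # species -> allele -> count
    allele_frequencies: dict[str, dict[str, float]]
    allele_percent_display: dict[str, dict[str, int]]
    contingency: pd.DataFrame  # allele x {spring, winter, variable?}
    concordant: int
    exceptions: list[dict[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "panel_size": self.panel_size,
            "species_counts": self.species_counts,
            "allele_counts": self.allele_counts,
            "allele_frequencies": self.allele_frequencies,
            "allele_percent_display": self.allele_percent_display,
            "contingency": self.contingency.to_dict(orient="index"),
            "concordant": self.concordant,
            "exceptions": self.exceptions,
        }


def genotype_panel(
    templates: list[Template],
    registry: Registry,
    params: CallerParams | None = None,
) -> tuple[pd.DataFrame, list[GenotypeReport]]:
    """Genotype every accession in a panel of templates.

    Templates sharing an accession-id prefix (``<accession>|<genome>``) form
    one sample. Returns one row per accession, ordered by accession id, plus
    the full reports. A corrupted record degrades only its own row (the
    caller reports ``unresolved`` rather than raising).
    """
    if not templates:
        raise ValueError("empty panel")
    keyed = sorted(templates, key=lambda t: t.id.split("|")[0])
    rows = []
    reports: list[GenotypeReport] = []
    for acc, group in groupby(keyed, key=lambda t: t.id.split("|")[0]):
        report = call_genotype(list(group), registry, params)
        reports.append(report)
        rows.append({
            "accession": acc,
            "a_call": report.a_call,
            "b_call": report.b_call,
            "species": ";".join(report.species),
            "habit": report.habit,
            "habit_confidence": report.habit_confidence,
            "flags": ";".join(report.flags),
        })
    table = pd.DataFrame(rows, columns=["accession", "a_call", "b_call",
                                        "species", "habit",
                                        "habit_confidence", "flags"])
    return table, reports


def habit_association(roster: list[RosterRow]) -> pd.DataFrame:
    """Allele × {spring, winter} contingency counts from habit-labelled rows.

    Rows without a habit label are excluded; alleles observed with both
    labels are marked ``variable``. No statistical test is applied (cell
    counts in this material are 2–5).
    """
    from .scaffolds import roster_allele

    counts: dict[str, dict[str, int]] = {}
    for row in roster:
        if row.habit not in ("spring", "winter"):
            continue
        allele = roster_allele(row)
        counts.setdefault(allele, {"spring": 0, "winter": 0})
        counts[allele][row.habit] += 1
    if not counts:
        return pd.DataFrame(columns=["spring", "winter", "association"])
    table = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    table["association"] = [
        "variable" if s > 0 and w > 0 else ("spring" if s else "winter")
        for s, w in zip(table["spring"], table["winter"])
    ]
    return table


def summarize(
    results: pd.DataFrame,
    roster: list[RosterRow],
    registry: Registry | None = None,
) -> PanelSummary:
    """Survey statistics from a genotyped panel and its roster.

    ``results`` and ``roster`` must be keyed by the same accession ids.
    Percentages for display are rounded half-up to integers, so 19 carriers
    among 61 accessions render as 31%.
    """
    by_acc = {r.accession: r for r in roster}
    missing = set(results["accession"]) - set(by_acc)
    if missing:
        raise KeyError(f"results contain accessions absent from roster: {sorted(missing)}")

    species_counts: dict[str, int] = {}
    allele_counts: dict[str, dict[str, int]] = {}
    for _, row in results.iterrows():
        sp = by_acc[row["accession"]].species
        species_counts[sp] = species_counts.get(sp, 0) + 1
        allele_counts.setdefault(sp, {})
        allele_counts[sp][row["a_call"]] = allele_counts[sp].get(row["a_call"], 0) + 1

    freqs = {
        sp: {al: n / species_counts[sp] for al, n in counts.items()}
        for sp, counts in allele_counts.items()
    }
    pct = {
        sp: {al: display_percent(n, species_counts[sp]) for al, n in counts.items()}
        for sp, counts in allele_counts.items()
    }

    contingency = habit_association(roster)

    concordant = 0
    exceptions: list[dict[str, str]] = []
    for _, row in results.iterrows():
        observed = by_acc[row["accession"]].habit
        predicted = row["habit"]
        if observed not in ("spring", "winter"):
            continue
        if predicted == observed or predicted == "variable":
            concordant += 1
        else:
            exceptions.append({
                "accession": row["accession"],
                "allele": row["a_call"],
                "predicted": predicted,
                "observed": observed,
            })

    return PanelSummary(
        panel_size=len(results),
        species_counts=species_counts,
        allele_counts=allele_counts,
        allele_frequencies=freqs,
        allele_percent_display=pct,
        contingency=contingency,
        concordant=concordant,
        exceptions=exceptions,
    )
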