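"""Standard-format readers and writers: FASTA, GFF3, roster TSV, reports.

FASTA handling goes through Biopython; sequences are normalized to
uppercase on read and rejected (with the offending position) if they
contain non-IUPAC characters. FASTA is written wrapped at 60 columns.
Feature annotations export as GFF3 (coordinates are 0-based half-open
internally and 1-based inclusive on write, per the GFF3 convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scaffolds import RosterRow
from .sequtils import IUPAC_BITS, Template

__all__ = [
    "FastaError", "read_fasta", "write_fasta", "template_to_record",
    "write_gff3", "read_roster", "write_roster", "write_report_json",
    "write_panel_tsv",
]

ROSTER_COLUMNS = ["accession", "species", "promoter_allele", "intron_state", "habit"]


class FastaError(ValueError):
    """Malformed FASTA input (bad characters, empty records, parse failure)."""


def read_fasta(path: str | Path) -> list[Template]:
    """Read FASTA records as templates, validating the alphabet.

    Lowercase input is accepted and normalized to uppercase; CRLF line
    endings are handled by the parser. A non-IUPAC character raises
    :class:`FastaError` naming the record and 0-based position.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    templates: list[Template] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython is permissive
        raise FastaError(f"{path}: cannot parse FASTA ({exc})") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    for rec in records:
        # keep the full header as the id so accession names containing
        # spaces ("TRI 1510|A") survive the round trip
        rec_id = rec.description or rec.id
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_BITS:
                raise FastaError(
                    f"{path}: record {rec_id!r}: non-IUPAC character {ch!r} "
                    f"at position {i}")
        if not seq:
            raise FastaError(f"{path}: record {rec_id!r} is empty")
        templates.append(Template(id=rec_id, seq=seq))
    return templates


def template_to_record(template: Template, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(template.seq), id=template.id, description=description)


def write_fasta(templates: Iterable[Template], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    """Write templates as FASTA wrapped at 60 columns."""
    descriptions = descriptions or {}
    path = Path(path)
    with path.open("w") as fh:
        for t in templates:
            desc = descriptions.get(t.id, "")
            header = f">{t.id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            for i in range(0, len(t.seq), 60):
                fh.write(t.seq[i:i + 60] + "\n")


def write_gff3(template: Template, path: str | Path, source: str = "vrncaps") -> None:
    """Export template features as GFF3 (1-based inclusive coordinates)."""
    type_map = {
        "primer_fwd": "primer_binding_site",
        "primer_rev": "primer_binding_site",
        "enzyme_site": "restriction_enzyme_recognition_site",
        "motif": "sequence_feature",
        "landmark": "region",
    }
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {template.id} 1 {len(template.seq)}\n")
        for f in sorted(template.features, key=lambda x: x.start):
            fh.write("\t".join([
                template.id, source, type_map.get(f.kind, "sequence_feature"),
                str(f.start + 1), str(f.end), ".",
                "-" if f.kind == "primer_rev" else "+", ".",
                f"ID={f.name};kind={f.kind}",
            ]) + "\n")


def read_roster(path: str | Path) -> list[RosterRow]:
    """Read an accession roster TSV (documented header: ROSTER_COLUMNS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"roster not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: roster missing columns {sorted(missing)}")
    return [
        RosterRow(
            accession=row["accession"], species=row["species"],
            promoter_allele=row["promoter_allele"],
            intron_state=row["intron_state"], habit=row["habit"],
        )
        for _, row in df.iterrows()
    ]


def write_roster(roster: list[RosterRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": r.accession, "species": r.species,
                "promoter_allele": r.promoter_allele,
                "intron_state": r.intron_state, "habit": r.habit,
            }
            for r in roster
        ],
        columns=ROSTER_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_report_json(report: Any, path: str | Path, *,
                      seed: int | None = None) -> None:
    """Serialize a report-like object (with .to_dict) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    if seed is not None and isinstance(payload, dict):
        payload = {"seed": seed, **payload}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_panel_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
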