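"""Shared low-level sequence machinery: IUPAC codes, templates, landmarks.

A :class:`Template` is the in-memory unit every other module operates on — a
plain uppercase DNA string plus a table of named landmarks (ATG start codon,
CArG box, intron-1 start, primer footprints) and a set of *protected*
intervals (assay footprints that background noise must never touch).
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

DNA_BASES = "ACGT"

#: 256-entry lookup table mapping ASCII byte -> IUPAC bitmask (0 = invalid).
_BIT_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in IUPAC_BITS.items():
    _BIT_LUT[ord(_c)] = _b
    _BIT_LUT[ord(_c.lower())] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return str(Seq(seq).reverse_complement())


def seq_to_bits(seq: str) -> np.ndarray:
    """Map a DNA string onto the IUPAC bitmask alphabet as a uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bits = _BIT_LUT[arr]
    if (bits == 0).any():
        pos = int(np.argmax(bits == 0))
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    return bits


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase `seq` and reject non-IUPAC characters, naming the position."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_BITS:
            raise ValueError(f"{name}: non-IUPAC character {ch!r} at position {i}")
    return up


@dataclass(frozen=True)
class Feature:
    """A named, typed interval on a template (half-open coordinates)."""

    name: str
    start: int
    end: int
    kind: str  # primer_fwd | primer_rev | enzyme_site | motif | landmark | region


@dataclass
class Template:
    """A DNA template with landmark and feature bookkeeping.

    ``landmarks`` are single positions used as edit anchors; they are
    re-projected whenever an edit shifts the sequence. ``protected`` marks
    the union of assay footprints (primer sites and expected amplicon spans)
    where background noise must not be introduced.
    """

    id: str
    seq: str
    landmarks: dict[str, int] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    protected: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def with_id(self, new_id: str) -> "Template":
        return replace(self, id=new_id)

    def copy(self) -> "Template":
        return Template(
            id=self.id,
            seq=self.seq,
            landmarks=dict(self.landmarks),
            features=list(self.features),
            protected=list(self.protected),
        )


def _shift(pos: int, at: int, delta: int) -> int | None:
    """Project a single coordinate through an edit at ``at`` with net ``delta``.

    Returns None if the position fell inside a deleted span.
    """
    if pos < at:
        return pos
    if delta < 0 and pos < at - delta:  # inside the deleted window
        return None
    return pos + delta


def project_through(template: Template, at: int, delta: int) -> None:
    """Re-project landmarks, features and protected intervals in place."""
    new_lm: dict[str, int] = {}
    for name, pos in template.landmarks.items():
        p = _shift(pos, at, delta)
        if p is not None:
            new_lm[name] = p
    template.landmarks = new_lm

    new_feats: list[Feature] = []
    for f in template.features:
        s = _shift(f.start, at, delta)
        e = _shift(f.end, at, delta)
        if delta < 0:
            # clip partially-deleted intervals instead of dropping them
            if s is None:
                s = at
            if e is None:
                e = at
        if s is not None and e is not None and e > s:
            new_feats.append(Feature(f.name, s, e, f.kind))
    template.features = new_feats

    new_prot: list[tuple[int, int]] = []
    for s0, e0 in template.protected:
        s = _shift(s0, at, delta)
        e = _shift(e0, at, delta)
        if delta < 0:
            if s is None:
                s = at
            if e is None:
                e = at
        if s is not None and e is not None and e > s:
            new_prot.append((s, e))
    template.protected = new_prot


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
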