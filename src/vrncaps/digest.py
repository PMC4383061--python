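"""Virtual restriction digestion and gel-band modelling.

Fragments are exact (cut-to-cut lengths that always sum to the amplicon
length); the gel model then drops fragments below a resolvability threshold
and merges near-identical sizes into one band of summed intensity — the
co-migration effect that, for example, superimposes a 198 bp fragment on a
200 bp band as a single, more intensely stained band.

Defaults: 100 bp resolvability (only fragments longer than that are scored
as bands) and 4 bp co-migration tolerance (198/200 superimpose; 119/130 or
119/138 remain separate bands).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pcr import Amplicon
from .registry import RestrictionEnzyme

__all__ = ["FragmentSet", "BandPattern", "GelModel", "find_sites", "digest",
           "to_band_pattern", "render_gel_lane"]


@dataclass(frozen=True)
class GelModel:
    resolvability: int = 100  # bp; smaller fragments run off / are not scored
    comigration_tol: int = 4  # bp; sizes this close merge into one band


@dataclass(frozen=True)
class FragmentSet:
    """Digest result: sorted cut positions and the fragment multiset."""

    amplicon_id: str
    length: int
    cuts: tuple[int, ...]
    fragments: tuple[int, ...]  # in template order, sums to `length`


@dataclass(frozen=True)
class BandPattern:
    """Gel-resolvable bands as (size, intensity), sorted descending."""

    bands: tuple[tuple[int, int], ...]

    def sizes(self) -> tuple[int, ...]:
        return tuple(b[0] for b in self.bands)


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sorted cut positions of `enzyme` on the forward strand.

    The enzymes used here (Msp I C^CGG, Taq I T^CGA) have palindromic
    recognition sequences, so a single-strand scan finds every site.
    Overlapping occurrences are all reported.
    """
    rec, off = enzyme.recognition, enzyme.cut_offset
    cuts: list[int] = []
    i = sequence.find(rec)
    while i != -1:
        cuts.append(i + off)
        i = sequence.find(rec, i + 1)
    return cuts


def digest(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> FragmentSet:
    """Cut an amplicon at every enzyme site; fragments partition the product."""
    cuts = find_sites(amplicon.seq, enzyme)
    bounds = [0] + cuts + [len(amplicon.seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentSet(
        amplicon_id=f"{amplicon.assay}@{amplicon.template_id}",
        length=len(amplicon.seq),
        cuts=tuple(cuts),
        fragments=fragments,
    )


def to_band_pattern(fragments, gel: GelModel | None = None) -> BandPattern:
    """Collapse a fragment multiset into gel bands.

    Fragments below the resolvability threshold are dropped; the remainder
    are chain-merged: any run of sizes in which consecutive sorted values
    differ by at most the co-migration tolerance forms a single band at the
    largest size with intensity equal to the number of co-migrating
    fragments.
    """
    gel = gel or GelModel()
    if hasattr(fragments, "fragments"):
        fragments = fragments.fragments
    sizes = sorted((f for f in fragments if f >= gel.resolvability), reverse=True)
    bands: list[tuple[int, int]] = []
    prev = None  # size of the most recently clustered fragment
    for s in sizes:
        if prev is not None and prev - s <= gel.comigration_tol:
            bands[-1] = (bands[-1][0], bands[-1][1] + 1)
        else:
            bands.append((s, 1))
        prev = s
    return BandPattern(bands=tuple(bands))


def render_gel_lane(pattern: BandPattern, label: str = "",
                    top: int = 1200, rows: int = 24) -> str:
    """Text rendering of one gel lane (log-scaled migration, for docs/CLI).

    Band intensity is drawn as bar thickness: ``====`` for a single
    fragment, ``####`` for co-migrating fragments.
    """
    import math

    lines = [f"lane: {label}" if label else "lane:"]
    if not pattern.bands:
        return "\n".join(lines + ["  (no bands >= threshold)"])
    lo = math.log(50)
    hi = math.log(max(top, max(s for s, _ in pattern.bands) + 100))
    grid: dict[int, tuple[int, int]] = {}
    for size, intensity in pattern.bands:
        r = int((hi - math.log(size)) / (hi - lo) * (rows - 1))
        grid[min(max(r, 0), rows - 1)] = (size, intensity)
    for r in range(rows):
        if r in grid:
            size, intensity = grid[r]
            bar = "####" if intensity > 1 else "===="
            lines.append(f"  {bar}  {size} bp" + (f" (x{intensity})" if intensity > 1 else ""))
        else:
            lines.append("  .")
    return "\n".join(lines)
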