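"""Virtual PCR: primer-site search under a mismatch model, amplicon assembly.

Primer binding sites are located on both strands with a bounded number of
mismatches and a mismatch-free 3'-terminal anchor (the polymerase extension
requirement). Amplicons are assembled with the primer sequences *substituted*
into the product — the mechanism that makes dCAPS assays work, because a
deliberately mismatched primer base becomes part of the product and can
complete (or fail to complete) a restriction site together with adjacent
template bases.

The search is vectorized over all windows with IUPAC-bitmask comparison;
tests hold it to a position-by-position brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .registry import MarkerAssay
from .sequtils import Template, revcomp, seq_to_bits

logger = logging.getLogger(__name__)

__all__ = ["BindingSite", "Amplicon", "PCRParams", "find_binding_sites", "amplify"]

MAX_PRODUCTS = 10


@dataclass(frozen=True)
class PCRParams:
    """Mismatch model defaults.

    ``max_mismatch=2`` admits the deliberate single mismatch of the VRN1F_R
    dCAPS primer while rejecting cross-genome priming; ``anchor_len=3``
    requires a perfect 3' clamp.
    """

    max_mismatch: int = 2
    anchor_len: int = 3


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site (template top-strand coordinates, half-open)."""

    template_id: str
    strand: str  # '+' : primer extends rightward; '-' : leftward
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...]  # primer 5'->3' coordinates, 0-based


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product with primer regions substituted in."""

    assay: str
    template_id: str
    start: int
    end: int
    seq: str = field(repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start


def find_binding_sites(
    template: Template | str,
    primer: str,
    max_mismatch: int = 2,
    anchor_len: int = 3,
) -> list[BindingSite]:
    """All annealing sites of `primer` on both strands of `template`.

    A '+' site means the primer matches the top strand read 5'->3' (and
    extension runs rightward); a '-' site means it matches the reverse
    complement (extension leftward). Mismatches are counted per primer
    position; the 3'-terminal ``anchor_len`` bases must match exactly.
    IUPAC ambiguity codes in the primer match their base sets.
    """
    if isinstance(template, Template):
        tid, seq = template.id, template.seq
    else:
        tid, seq = "<seq>", template
    m = len(primer)
    if m < anchor_len:
        raise ValueError(f"primer length {m} < anchor_len {anchor_len}")
    if len(seq) < m:
        return []

    tbits = seq_to_bits(seq)
    windows = sliding_window_view(tbits, m)  # (L-m+1, m)
    sites: list[BindingSite] = []

    for strand, pseq in (("+", primer), ("-", revcomp(primer))):
        pbits = seq_to_bits(pseq)
        mism = (windows & pbits) == 0  # True where primer base cannot pair
        counts = mism.sum(axis=1)
        # primer 3' end: last anchor_len window positions on '+', first on '-'
        if strand == "+":
            anchor_bad = mism[:, m - anchor_len:].any(axis=1)
        else:
            anchor_bad = mism[:, :anchor_len].any(axis=1)
        hits = np.nonzero((counts <= max_mismatch) & ~anchor_bad)[0]
        for i in hits:
            wpos = np.nonzero(mism[i])[0]
            if strand == "+":
                ppos = tuple(int(p) for p in wpos)
            else:
                ppos = tuple(sorted(m - 1 - int(p) for p in wpos))
            sites.append(BindingSite(tid, strand, int(i), int(i) + m,
                                     int(counts[i]), ppos))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: Template,
    assay: MarkerAssay,
    params: PCRParams | None = None,
) -> list[Amplicon]:
    """Virtual PCR of one assay on one template.

    One amplicon is produced per convergent forward/reverse site pair whose
    span does not exceed the assay's ``max_product`` cutoff; the empty list
    means "no product". Product sequences carry the primer bases verbatim at
    both ends (5' end equals the forward primer, 3' end the reverse
    complement of the reverse primer).
    """
    params = params or PCRParams()
    fwd_sites = find_binding_sites(template, assay.forward,
                                   params.max_mismatch, params.anchor_len)
    rev_sites = find_binding_sites(template, assay.reverse,
                                   params.max_mismatch, params.anchor_len)
    max_len = assay.max_product or len(template.seq)

    products: list[Amplicon] = []

    def _emit(start: int, end: int, top_strand: bool) -> None:
        inner = template.seq[start + len(assay.forward): end - len(assay.reverse)] \
            if top_strand else \
            revcomp(template.seq[start + len(assay.reverse): end - len(assay.forward)])
        seq = assay.forward + inner + revcomp(assay.reverse)
        products.append(Amplicon(assay.name, template.id, start, end, seq))

    # forward primer on +, reverse primer on - (product read on top strand)
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            span = r.end - f.start
            if r.start >= f.end and span <= max_len:
                _emit(f.start, r.end, top_strand=True)
    # reverse primer on +, forward primer on - (product read on bottom strand)
    for r in (s for s in rev_sites if s.strand == "+"):
        for f in (s for s in fwd_sites if s.strand == "-"):
            span = f.end - r.start
            if f.start >= r.end and span <= max_len:
                _emit(r.start, f.end, top_strand=False)

    if len(products) > MAX_PRODUCTS:
        logger.warning(
            "assay %s on %s: %d products, truncating to %d (combinatorial explosion)",
            assay.name, template.id, len(products), MAX_PRODUCTS,
        )
        products = products[:MAX_PRODUCTS]
    return products
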