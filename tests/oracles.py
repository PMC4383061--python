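"""Independent brute-force oracles used to cross-check the search engines.

These deliberately share no code with the package implementation: primer
matching is a per-position python loop over explicit IUPAC base sets, and
enzyme-site finding is a sliding-window string comparison.
"""

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_binding_sites(template: str, primer: str, max_mismatch: int = 2,
                        anchor_len: int = 3):
    """All (strand, start, mismatch_count) tuples, scanned position by position."""
    m = len(primer)
    out = []
    for strand in ("+", "-"):
        p = primer if strand == "+" else rc(primer)
        # primer 3' end sits at the window's right edge on '+', left edge on '-'
        anchor_idx = range(m - anchor_len, m) if strand == "+" else range(anchor_len)
        for i in range(len(template) - m + 1):
            window = template[i:i + m]
            mism = [j for j in range(m) if window[j] not in IUPAC_SETS[p[j]]]
            if len(mism) <= max_mismatch and not any(j in mism for j in anchor_idx):
                out.append((strand, i, len(mism)))
    return sorted(out, key=lambda x: (x[1], x[0]))


def brute_cut_positions(sequence: str, recognition: str, cut_offset: int):
    """Sliding-window scan for recognition sites; overlapping hits included."""
    n = len(recognition)
    return [i + cut_offset for i in range(len(sequence) - n + 1)
            if sequence[i:i + n] == recognition]
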