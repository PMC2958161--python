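"""Independent brute-force oracles used to cross-check the scanner.

The regex route shares no code with sopescan's subset-rule matcher: patterns
are compiled to character classes and matched with overlapping lookahead on
plain ACGT sequences.
"""

import re

_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(_CLASS[c] for c in pattern) + "))")


def oracle_scan(sequence: str, pattern: str, name: str, both_strands: bool = True):
    """All (start, end, strand) triples where the pattern matches, with
    palindromic double-matches collapsed to a single '+' entry."""
    fwd_re = _regex(pattern)
    # a window matches on the minus strand iff it matches the reverse
    # complement of the pattern read as a forward-strand regex
    rc_pattern = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(pattern)
    )
    rev_re = _regex(rc_pattern)
    L = len(pattern)
    fwd = {m.start() for m in fwd_re.finditer(sequence)}
    rev = {m.start() for m in rev_re.finditer(sequence)} if both_strands else set()
    out = []
    for i in sorted(fwd | rev):
        w = sequence[i : i + L]
        if i in fwd and i in rev and _rc(w) == w:
            out.append((name, i, i + L, "+"))
            continue
        if i in fwd:
            out.append((name, i, i + L, "+"))
        if i in rev:
            out.append((name, i, i + L, "-"))
    return out


def oracle_scan_all(sequence: str, defs):
    """Oracle hits for a list of IUPAC box definitions, scanner sort order."""
    out = []
    for d in defs:
        out.extend(oracle_scan(sequence, d.pattern, d.name, d.both_strands))
    out.sort(key=lambda t: (t[1], t[0], t[3]))
    return out
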