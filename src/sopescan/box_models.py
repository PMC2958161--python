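"""The four SOPE binding-site classes and degenerate-pattern scanning.

The sensory organ precursor enhancer (SOPE) is operationalised as a cluster
of four binding-site classes found in achaete-scute UTRs:

* **E box** — bHLH (Achaete/Scute/Asense) site, canonical ``CANNTG``;
* **N box** — Hairy/Enhancer-of-split repressor site, canonical ``CACNAG``;
* **α box** — NF-κB/Dorsal-class site, ``GGGWWWNCC``;
* **β box** — AT-rich element of unknown binding factor, modelled as a
  window rule (width 8, ≥ 85 % A/T) rather than a consensus.

All four definitions are configuration-overridable: the canonical strings are
field defaults, not measurements.  Matching uses the IUPAC subset rule — a
window letter matches a pattern letter iff its base set is contained in the
pattern letter's base set — so an ``N`` in a draft-genome sequence matches
only an ``N``-compatible pattern position unless the wildcard policy is
requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Iterable, Optional, Sequence

from .seq_io import Region

IUPAC_DNA: dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide: {exc.args[0]!r}") from None


def _validate_iupac(text: str, what: str) -> None:
    for ch in text:
        if ch not in IUPAC_DNA:
            raise ValueError(f"{what} contains non-IUPAC letter {ch!r}")


@dataclass(frozen=True)
class BoxDefinition:
    """One binding-site class: either an IUPAC consensus or an AT-rich window rule."""

    name: str
    kind: str  # "iupac_pattern" | "at_rich_window"
    pattern: Optional[str] = None
    width: Optional[int] = None
    min_at_fraction: Optional[float] = None
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.kind == "iupac_pattern":
            if not self.pattern:
                raise ValueError(f"box {self.name!r}: empty pattern")
            _validate_iupac(self.pattern, f"box {self.name!r} pattern")
        elif self.kind == "at_rich_window":
            if self.width is None or self.width < 4:
                raise ValueError(f"box {self.name!r}: width must be >= 4")
            if self.min_at_fraction is None or not (0 < self.min_at_fraction <= 1):
                raise ValueError(f"box {self.name!r}: min_at_fraction must be in (0, 1]")
        else:
            raise ValueError(f"box {self.name!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class BoxHit:
    """A located box instance, always reported in forward-strand coordinates.

    ``matched_text`` is the forward-strand slice of the scanned sequence even
    for minus-strand hits.
    """

    box_name: str
    region: Region
    strand: str
    matched_text: str


def iupac_match(pattern: str, window: str, n_policy: str = "strict") -> bool:
    """Subset-rule comparison of an IUPAC window against an IUPAC pattern.

    True iff at every position the window letter's base set is a subset of the
    pattern letter's base set.  With ``n_policy="wildcard"`` an ambiguous
    window letter instead matches when the two base sets merely intersect.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    _validate_iupac(pattern, "pattern")
    _validate_iupac(window, "window")
    if n_policy not in ("strict", "wildcard"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    for p, w in zip(pattern, window):
        ps, ws = IUPAC_DNA[p], IUPAC_DNA[w]
        if n_policy == "strict":
            if not ws <= ps:
                return False
        else:
            if not (ws & ps):
                return False
    return True


def _match_fast(psets: tuple, window: str, wildcard: bool) -> bool:
    # precompiled inner loop used by the scanner; assumes window is IUPAC-valid
    for ps, w in zip(psets, window):
        ws = IUPAC_DNA[w]
        if wildcard:
            if not (ws & ps):
                return False
        elif not ws <= ps:
            return False
    return True


def scan_iupac_boxes(
    sequence: str,
    defs: Sequence[BoxDefinition],
    n_policy: str = "strict",
) -> list[BoxHit]:
    """Scan every window of each pattern on both strands.

    Hits are reported in forward-strand coordinates, sorted by
    ``(start, box_name, strand)``.  A locus matching on both strands whose
    site is its own reverse complement yields a single ``+`` hit (palindrome
    deduplication); a degenerate pattern matching a non-palindromic site on
    both strands yields two hits.  Overlapping hits are all reported —
    relevance is the cluster caller's decision, not the scanner's.
    """
    sequence = sequence.upper()
    _validate_iupac(sequence, "sequence")
    wildcard = n_policy == "wildcard"
    hits: list[BoxHit] = []
    for bdef in defs:
        if bdef.kind != "iupac_pattern":
            raise ValueError(f"box {bdef.name!r} is not an iupac_pattern definition")
        pat = bdef.pattern
        L = len(pat)
        psets = tuple(IUPAC_DNA[c] for c in pat)
        for i in range(len(sequence) - L + 1):
            w = sequence[i : i + L]
            fwd = _match_fast(psets, w, wildcard)
            rev = False
            if bdef.both_strands:
                rc = reverse_complement(w)
                rev = _match_fast(psets, rc, wildcard)
            region = Region(i, i + L)
            if fwd and rev and rc == w:
                hits.append(BoxHit(bdef.name, region, "+", w))
                continue
            if fwd:
                hits.append(BoxHit(bdef.name, region, "+", w))
            if rev:
                hits.append(BoxHit(bdef.name, Region(i, i + L, "-"), "-", w))
    hits.sort(key=lambda h: (h.region.start, h.box_name, h.strand))
    return hits


def scan_at_rich(sequence: str, bdef: BoxDefinition) -> list[BoxHit]:
    """Find maximal AT-rich regions under a sliding-window rule.

    Every window of ``bdef.width`` whose A/T fraction is at least
    ``bdef.min_at_fraction`` qualifies; overlapping or adjacent qualifying
    windows are merged and each merged region is trimmed to its outermost A/T
    bases, then reported as one strandless hit (strand "+").  A width larger
    than the sequence yields an empty result, not an error.
    """
    if bdef.kind != "at_rich_window":
        raise ValueError(f"box {bdef.name!r} is not an at_rich_window definition")
    sequence = sequence.upper()
    _validate_iupac(sequence, "sequence")
    w = bdef.width
    n = len(sequence)
    if w > n:
        return []
    is_at = [1 if c in "AT" else 0 for c in sequence]
    need = bdef.min_at_fraction * w
    # rolling A/T count over windows
    count = sum(is_at[:w])
    starts = []
    for i in range(n - w + 1):
        if i > 0:
            count += is_at[i + w - 1] - is_at[i - 1]
        if count >= need - 1e-9:
            starts.append(i)
    hits: list[BoxHit] = []
    i = 0
    while i < len(starts):
        s = starts[i]
        e = s + w
        j = i + 1
        while j < len(starts) and starts[j] <= e:  # overlap or adjacency
            e = starts[j] + w
            j += 1
        # trim to the outermost A/T bases of the merged span
        while s < e and not is_at[s]:
            s += 1
        while e > s and not is_at[e - 1]:
            e -= 1
        hits.append(BoxHit(bdef.name, Region(s, e), "+", sequence[s:e]))
        i = j
    return hits


def scan_boxes(
    sequence: str,
    defs: Sequence[BoxDefinition],
    n_policy: str = "strict",
) -> list[BoxHit]:
    """Dispatch each definition to the appropriate scanner; merged, sorted output."""
    iupac = [d for d in defs if d.kind == "iupac_pattern"]
    hits = scan_iupac_boxes(sequence, iupac, n_policy=n_policy) if iupac else []
    for d in defs:
        if d.kind == "at_rich_window":
            hits.extend(scan_at_rich(sequence, d))
    hits.sort(key=lambda h: (h.region.start, h.box_name, h.strand))
    return hits


def default_box_set() -> list[BoxDefinition]:
    """The four default SOPE box definitions (E, alpha, beta, N)."""
    return [
        BoxDefinition(name="E", kind="iupac_pattern", pattern="CANNTG", both_strands=True),
        BoxDefinition(name="alpha", kind="iupac_pattern", pattern="GGGWWWNCC", both_strands=True),
        BoxDefinition(name="beta", kind="at_rich_window", width=8, min_at_fraction=0.85),
        BoxDefinition(name="N", kind="iupac_pattern", pattern="CACNAG", both_strands=True),
    ]


def _base_probs(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def pattern_match_probability(pattern: str, gc: float = 0.5) -> float:
    """Per-window single-strand match probability on random i.i.d. DNA of the
    given GC content (G and C equiprobable, likewise A and T)."""
    _validate_iupac(pattern, "pattern")
    probs = _base_probs(gc)
    return prod(sum(probs[b] for b in IUPAC_DNA[c]) for c in pattern)


def palindromic_match_probability(pattern: str, gc: float = 0.5) -> float:
    """Probability a random window matches ``pattern`` AND is its own reverse
    complement.  Zero for odd-length patterns (the centre base cannot
    self-complement)."""
    _validate_iupac(pattern, "pattern")
    probs = _base_probs(gc)
    L = len(pattern)
    if L % 2 == 1:
        return 0.0
    p = 1.0
    for i in range(L // 2):
        si = IUPAC_DNA[pattern[i]]
        sj = IUPAC_DNA[pattern[L - 1 - i]]
        p *= sum(
            probs[x] * probs[_COMPLEMENT[x]] for x in si if _COMPLEMENT[x] in sj
        )
    return p


def expected_hit_density(bdef: BoxDefinition, gc: float = 0.5) -> float:
    """Expected scanner hits per window on random i.i.d. DNA.

    Accounts for both strands and for palindrome deduplication:
    ``p_fwd + p_rev − p_palindromic`` when both strands are scanned.  Defined
    only for IUPAC-pattern definitions.
    """
    if bdef.kind != "iupac_pattern":
        raise ValueError("analytic density defined only for IUPAC patterns")
    p = pattern_match_probability(bdef.pattern, gc)
    if not bdef.both_strands:
        return p
    p_rev = pattern_match_probability(reverse_complement(bdef.pattern), gc)
    return p + p_rev - palindromic_match_probability(bdef.pattern, gc)


def _both_strand_match_probability(pattern: str, gc: float) -> float:
    """Probability a random window matches the pattern on BOTH strands, i.e.
    matches the position-wise intersection of the pattern and its reverse
    complement."""
    probs = _base_probs(gc)
    rc = reverse_complement(pattern)
    p = 1.0
    for a, b in zip(pattern, rc):
        inter = IUPAC_DNA[a] & IUPAC_DNA[b]
        if not inter:
            return 0.0
        p *= sum(probs[x] for x in inter)
    return p


def hit_count_variance(bdef: BoxDefinition, gc: float = 0.5) -> float:
    """Per-window variance of the scanner's hit count on random i.i.d. DNA.

    A window can yield 0, 1 or 2 hits: a non-palindromic site matching on
    both strands is reported twice, so the count is over-dispersed relative
    to Poisson (markedly so for the E box, where every forward match also
    matches in reverse).  Needed for calibrated z-scores of background hit
    counts.
    """
    if bdef.kind != "iupac_pattern":
        raise ValueError("analytic variance defined only for IUPAC patterns")
    pf = pattern_match_probability(bdef.pattern, gc)
    if not bdef.both_strands:
        return pf * (1 - pf)
    pr = pattern_match_probability(reverse_complement(bdef.pattern), gc)
    pb = _both_strand_match_probability(bdef.pattern, gc)
    ppal = palindromic_match_probability(bdef.pattern, gc)
    mean = pf + pr - ppal
    second_moment = pf + pr + 2 * pb - 3 * ppal
    return second_moment - mean * mean
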