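"""Heterotypic cluster calling: grouping box hits into candidate SOPEs.

A candidate sensory organ precursor enhancer is a chain of box hits in which
consecutive hits (ordered by start) are separated by at most ``gap_max``
bases, containing at least ``min_boxes`` hits of at least ``min_types``
distinct classes.  The defaults (450 bp, 4 boxes, 3 classes) admit all five
published arthropod SOPEs — 5–13 boxes of 3–4 classes over 246–1,052 bp —
while rejecting isolated hits.

Localisation relative to the ORF uses the gap convention: the distance is the
number of bases strictly between the cluster and the start/stop codon, which
reproduces the field's "N bp upstream of the start codon" phrasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seq_io import OrfAnnotation, Region, to_one_based
from .box_models import BoxHit


@dataclass(frozen=True)
class ClusterParams:
    gap_max: int = 450
    min_boxes: int = 4
    min_types: int = 3

    def __post_init__(self) -> None:
        if self.gap_max < 0:
            raise ValueError("gap_max must be >= 0")
        if self.min_boxes < 1:
            raise ValueError("min_boxes must be >= 1")
        if self.min_types < 1:
            raise ValueError("min_types must be >= 1")


@dataclass(frozen=True)
class SopeLocation:
    """ORF-relative placement of a cluster.

    ``utr_side`` is one of ``five_prime``, ``three_prime``,
    ``overlapping_orf``.  For 5' clusters ``upstream_distance`` is the number
    of bases between cluster end and the start codon; for 3' clusters
    ``downstream_near``/``downstream_far`` bound the cluster relative to the
    stop codon.
    """

    utr_side: str
    upstream_distance: Optional[int] = None
    downstream_near: Optional[int] = None
    downstream_far: Optional[int] = None

    def describe(self) -> str:
        if self.utr_side == "five_prime":
            return f"{self.upstream_distance} bp upstream of the start codon"
        if self.utr_side == "three_prime":
            return (
                f"between {self.downstream_near} bp and {self.downstream_far} bp "
                "downstream of the stop codon"
            )
        return "overlapping the ORF"


@dataclass(frozen=True)
class SopeCall:
    """A called cluster: span, member hits, per-class composition."""

    region: Region
    hits: tuple
    counts: dict
    n_types: int
    span_bp: int
    location: Optional[SopeLocation] = None

    def with_location(self, location: SopeLocation) -> "SopeCall":
        return SopeCall(
            region=self.region,
            hits=self.hits,
            counts=self.counts,
            n_types=self.n_types,
            span_bp=self.span_bp,
            location=location,
        )


def _make_call(chain: list) -> SopeCall:
    start = min(h.region.start for h in chain)
    end = max(h.region.end for h in chain)
    counts: dict = {}
    for h in chain:
        counts[h.box_name] = counts.get(h.box_name, 0) + 1
    counts = dict(sorted(counts.items()))
    return SopeCall(
        region=Region(start, end),
        hits=tuple(chain),
        counts=counts,
        n_types=len(counts),
        span_bp=end - start,
    )


def call_clusters(hits: Sequence[BoxHit], params: ClusterParams) -> list[SopeCall]:
    """Single-linkage chaining of box hits into clusters.

    Consecutive hits (by start) join one chain iff the gap between the chain's
    rightmost end and the next start is at most ``gap_max``; chains failing
    ``min_boxes`` or ``min_types`` are discarded.  Chains are maximal and the
    surviving clusters are returned in coordinate order; their regions never
    overlap.  Empty input yields empty output.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.region.start, h.region.end, h.box_name))
    chains: list[list] = []
    chain = [ordered[0]]
    max_end = ordered[0].region.end
    for h in ordered[1:]:
        if h.region.start - max_end <= params.gap_max:
            chain.append(h)
        else:
            chains.append(chain)
            chain = [h]
        max_end = max(max_end, h.region.end)
    chains.append(chain)
    calls = []
    for ch in chains:
        names = {h.box_name for h in ch}
        if len(ch) >= params.min_boxes and len(names) >= params.min_types:
            calls.append(_make_call(ch))
    calls.sort(key=lambda c: c.region.start)
    return calls


def localize_sope(call: SopeCall, orf: OrfAnnotation, seq_length: int) -> SopeLocation:
    """Place a cluster relative to the ORF in the gap convention.

    A cluster wholly 5' of the ORF reports ``upstream_distance`` =
    ORF start − cluster end; one wholly 3' reports ``downstream_near`` =
    cluster start − ORF end and ``downstream_far`` = cluster end − ORF end;
    anything else is ``overlapping_orf``.
    """
    if call.region.end > seq_length:
        raise ValueError(
            f"cluster [{call.region.start}, {call.region.end}) exceeds "
            f"sequence length {seq_length}"
        )
    o = orf.orf
    if call.region.end <= o.start:
        return SopeLocation("five_prime", upstream_distance=o.start - call.region.end)
    if call.region.start >= o.end:
        return SopeLocation(
            "three_prime",
            downstream_near=call.region.start - o.end,
            downstream_far=call.region.end - o.end,
        )
    return SopeLocation("overlapping_orf")


def calls_to_bed(calls: Sequence[SopeCall], chrom: str) -> list[tuple]:
    """BED6 rows (name "SOPE") for a sequence's cluster calls."""
    return [
        (chrom, c.region.start, c.region.end, "SOPE", 0, "+")
        for c in calls
    ]


def call_report_row(call: SopeCall, chrom: str) -> dict:
    """One prose-ready report row: 1-based span, composition, location."""
    start1, end1 = to_one_based(call.region)
    row = {
        "sequence": chrom,
        "start": start1,
        "end": end1,
        "span_bp": call.span_bp,
        "n_boxes": len(call.hits),
        "n_types": call.n_types,
        "counts": dict(call.counts),
    }
    if call.location is not None:
        row["utr_side"] = call.location.utr_side
        row["location"] = call.location.describe()
    return row
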