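"""Synthetic transcripts and proteins with known ground truth.

The generators emulate the data structure the analysis assumes: random DNA
backgrounds of configurable base composition carrying planted E/α/β/N box
instances at known coordinates inside a designated UTR, and proteins whose
C-terminal 16-mer matches the ASH reference at a controlled number of
positions, with or without a planted Ase motif.  Every generator is a pure
function of its arguments, seed included.

Background composition defaults to GC = 0.45 — insect UTRs run AT-rich, and
an AT-shifted background deliberately exposes the β-box scanner's
false-positive behaviour.  Planted box instances fill pattern degeneracies
uniformly at random (seeded), with an option to force the exact CAGCTG logo
for E boxes, mirroring the observation that the full logo appears in only a
minority of real E boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seq_io import (
    NucleotideRecord,
    ProteinRecord,
    Region,
    STOP_CODONS,
    find_orf,
)
from .box_models import (
    BoxDefinition,
    BoxHit,
    IUPAC_DNA,
    default_box_set,
    expected_hit_density,
    hit_count_variance,
    iupac_match,
    scan_boxes,
)
from .sope_caller import ClusterParams, call_clusters
from .protein_features import (
    ASH_CTERM_REFERENCE,
    measure_protein,
)

_BASES = "ACGT"
_NON_STOP_CODONS = tuple(
    sorted(
        "".join(c)
        for c in product(_BASES, repeat=3)
        if "".join(c) not in STOP_CODONS
    )
)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# residues absent from the C-terminal reference: safe fillers that can never
# match it at any alignment offset
_NON_REFERENCE_AA = tuple(sorted(set(_AA20) - set(ASH_CTERM_REFERENCE)))
_ASE_MOTIF_INSTANCE = "VKSEI"

SeedLike = Union[int, Sequence[int], np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantPlan:
    """Where and what to plant inside one designated UTR.

    ``planted_boxes`` is an ordered list of (box_name, offset-within-UTR,
    concrete instance text); instances must be mutually non-overlapping and
    must match their box definitions.
    """

    utr_side: str  # five_prime | three_prime
    planted_boxes: tuple
    utr_length: int
    background_gc: float = 0.45

    def __post_init__(self) -> None:
        if self.utr_side not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown utr_side {self.utr_side!r}")
        if not (0.0 <= self.background_gc <= 1.0):
            raise ValueError("background_gc must be in [0, 1]")
        prev_end = -1
        for name, off, text in sorted(self.planted_boxes, key=lambda t: t[1]):
            if off < 0 or off + len(text) > self.utr_length:
                raise ValueError(f"plant {name!r} at {off} exceeds UTR bounds")
            if off < prev_end:
                raise ValueError(f"plant {name!r} at {off} overlaps a previous plant")
            prev_end = off + len(text)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth bound to one emitted record."""

    record_id: str
    orf: Optional[Region] = None
    planted_hits: tuple = ()
    expected_cluster_span: Optional[tuple] = None  # (start, end) transcript coords
    utr_side: Optional[str] = None
    protein_label: Optional[str] = None
    cterm_matches: Optional[int] = None
    motif: Optional[bool] = None


def random_dna(length: int, gc: float, seed: SeedLike) -> str:
    """Independent base draws with P(G)+P(C) = gc, split evenly within pairs."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    if length == 0:
        return ""
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def draw_box_instance(
    bdef: BoxDefinition, rng: np.random.Generator, force_text: Optional[str] = None
) -> str:
    """A concrete instance of a box definition, degeneracies filled uniformly.

    For AT-rich window definitions the instance is an A/T string of the
    definition's width.  ``force_text`` overrides the draw (validated).
    """
    if force_text is not None:
        _check_instance(bdef, force_text)
        return force_text
    if bdef.kind == "iupac_pattern":
        return "".join(
            sorted(IUPAC_DNA[c])[rng.integers(len(IUPAC_DNA[c]))] for c in bdef.pattern
        )
    return "".join("AT"[rng.integers(2)] for _ in range(bdef.width))


def _check_instance(bdef: BoxDefinition, text: str) -> None:
    if bdef.kind == "iupac_pattern":
        if not iupac_match(bdef.pattern, text):
            raise ValueError(f"{text!r} does not match box {bdef.name!r}")
    else:
        at = sum(1 for c in text if c in "AT")
        if len(text) < bdef.width or at / len(text) < bdef.min_at_fraction:
            raise ValueError(f"{text!r} is not AT-rich enough for box {bdef.name!r}")


def _orf_sequence(orf_length: int, rng: np.random.Generator) -> str:
    n_mid = orf_length // 3 - 2
    mid = "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(len(_NON_STOP_CODONS), size=n_mid)
    )
    return "ATG" + mid + "TAA"


def synth_transcript(
    plan: PlantPlan,
    orf_length: int = 300,
    seed: SeedLike = 0,
    box_defs: Optional[Sequence[BoxDefinition]] = None,
    record_id: str = "synthetic_transcript",
    max_retries: int = 100,
) -> tuple[NucleotideRecord, SyntheticTruth]:
    """Emit a transcript [5' UTR][ORF][3' UTR] with planted box instances.

    The planted ORF is guaranteed to be the unique longest ORF of the emitted
    transcript: backgrounds that create a longer (or equal, earlier) spurious
    ORF are rejected and redrawn, up to ``max_retries`` times.  The truth
    records exact planted-hit coordinates in transcript coordinates and the
    expected cluster span (first planted start to last planted end).
    """
    if orf_length < 6 or orf_length % 3 != 0:
        raise ValueError("orf_length must be >= 6 and divisible by 3")
    defs = {d.name: d for d in (box_defs if box_defs is not None else default_box_set())}
    for name, off, text in plan.planted_boxes:
        if name in defs:
            _check_instance(defs[name], text)
    base_seed = np.random.default_rng(seed).integers(2**31)
    for attempt in range(max_retries):
        rng = np.random.default_rng([int(base_seed), attempt])
        utr = list(random_dna(plan.utr_length, plan.background_gc, rng))
        for name, off, text in plan.planted_boxes:
            utr[off : off + len(text)] = text
        utr_text = "".join(utr)
        orf_seq = _orf_sequence(orf_length, rng)
        if plan.utr_side == "five_prime":
            seq = utr_text + orf_seq
            orf_region = Region(plan.utr_length, plan.utr_length + orf_length)
            shift = 0
        else:
            seq = orf_seq + utr_text
            orf_region = Region(0, orf_length)
            shift = orf_length
        record = NucleotideRecord(id=record_id, sequence=seq)
        found = find_orf(record)
        if found is None or found.orf != orf_region:
            continue
        planted = tuple(
            BoxHit(name, Region(off + shift, off + shift + len(text)), "+", text)
            for name, off, text in plan.planted_boxes
        )
        span = None
        if planted:
            span = (
                min(h.region.start for h in planted),
                max(h.region.end for h in planted),
            )
        truth = SyntheticTruth(
            record_id=record_id,
            orf=orf_region,
            planted_hits=planted,
            expected_cluster_span=span,
            utr_side=plan.utr_side if planted else None,
        )
        return record, truth
    raise RuntimeError(
        f"could not emit a transcript whose planted ORF is the unique longest "
        f"within {max_retries} retries"
    )


def _expected_label(cterm_matches: int, motif: bool, cterm_min: float = 0.5) -> str:
    if motif:
        return "ase"
    if cterm_matches / 16 >= cterm_min:
        return "ASH"
    return "indeterminate"


def synth_protein(
    label: str,
    cterm_matches: int,
    motif: bool,
    length: int = 200,
    seed: SeedLike = 0,
    record_id: str = "synthetic_protein",
    max_retries: int = 100,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Emit a protein whose measured evidence equals the planted parameters.

    The C-terminal 16-mer equals the ASH reference at exactly
    ``cterm_matches`` positions (mismatches drawn from residues absent from
    the reference, so no other tail window can score higher); an Ase-motif
    instance is inserted iff ``motif``.  When ``motif`` is false, lysine is
    excluded from the random background, which makes an accidental motif
    impossible.  The emitted protein is re-measured before return and must
    reproduce (identity = k/16, motif flag) exactly.
    """
    if not (0 <= cterm_matches <= 16):
        raise ValueError("cterm_matches must be in [0, 16]")
    if length < 30:
        raise ValueError("length must be >= 30")
    expected = _expected_label(cterm_matches, motif)
    if label != expected:
        raise ValueError(
            f"label {label!r} inconsistent with (cterm_matches={cterm_matches}, "
            f"motif={motif}); expected {expected!r}"
        )
    ref = ASH_CTERM_REFERENCE
    filler = [a for a in _NON_REFERENCE_AA if motif or a != "K"]
    background = [a for a in _AA20 if motif or a != "K"]
    base_seed = np.random.default_rng(seed).integers(2**31)
    for attempt in range(max_retries):
        rng = np.random.default_rng([int(base_seed), attempt])
        tail_len = min(40, length)
        # [body (free)][pre-tail (non-reference fillers)][16-mer]
        body = "".join(
            background[i] for i in rng.integers(len(background), size=length - tail_len)
        )
        pre = "".join(
            filler[i] for i in rng.integers(len(filler), size=tail_len - 16)
        )
        cterm = list(ref)
        mism = rng.choice(16, size=16 - cterm_matches, replace=False)
        for pos in sorted(int(m) for m in mism):
            choices = [a for a in filler if a != ref[pos]]
            cterm[pos] = choices[rng.integers(len(choices))]
        seq = body + pre + "".join(cterm)
        if motif:
            ins = min(2, max(0, len(seq) - tail_len - len(_ASE_MOTIF_INSTANCE)))
            seq = seq[:ins] + _ASE_MOTIF_INSTANCE + seq[ins + len(_ASE_MOTIF_INSTANCE):]
        record = ProteinRecord(id=record_id, sequence=seq)
        ev = measure_protein(seq)
        ok = (
            ev.cterm is not None
            and ev.cterm.n_identical == cterm_matches
            and bool(ev.ase_motif_hits) == motif
            and ev.label == label
        )
        if ok:
            truth = SyntheticTruth(
                record_id=record_id,
                protein_label=label,
                cterm_matches=cterm_matches,
                motif=motif,
            )
            return record, truth
    raise RuntimeError("could not emit a protein reproducing the planted evidence")


def make_default_plan(
    utr_length: int = 600,
    utr_side: str = "five_prime",
    background_gc: float = 0.45,
    exact_consensus: bool = True,
    seed: SeedLike = 0,
    box_defs: Optional[Sequence[BoxDefinition]] = None,
) -> PlantPlan:
    """A five-box arrangement (E, α, β, E, N) spread over the UTR.

    With ``exact_consensus`` the instances are fixed canonical texts
    (E = CAGCTG, α = GGGAAAACC, β = ATATATAT, N = CACAAG); otherwise
    degeneracies are filled uniformly at random (seeded).
    """
    defs = {d.name: d for d in (box_defs if box_defs is not None else default_box_set())}
    rng = _rng(seed)
    fixed = {"E": "CAGCTG", "alpha": "GGGAAAACC", "beta": "ATATATAT", "N": "CACAAG"}
    order = ["E", "alpha", "beta", "E", "N"]
    offsets = [50, 180, 310, 440, 520]
    if utr_length < offsets[-1] + 10:
        raise ValueError("utr_length too short for the default arrangement")
    boxes = []
    for name, off in zip(order, offsets):
        text = fixed[name] if exact_consensus else draw_box_instance(defs[name], rng)
        boxes.append((name, off, text))
    return PlantPlan(
        utr_side=utr_side,
        planted_boxes=tuple(boxes),
        utr_length=utr_length,
        background_gc=background_gc,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    """Recall/precision of the scan+call pipeline on planted clusters, plus
    per-pattern background-hit calibration against the analytic expectation."""

    recall: float
    precision: float
    n_planted: int
    n_recovered: int
    n_called: int
    n_transcripts: int
    box_stats: pd.DataFrame  # per IUPAC box: observed vs expected background hits

    def summary(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "n_planted": self.n_planted,
            "n_recovered": self.n_recovered,
            "n_called": self.n_called,
            "n_transcripts": self.n_transcripts,
        }


def benchmark_recovery(
    n_transcripts: int = 100,
    utr_length: int = 600,
    background_gc: float = 0.45,
    exact_consensus: bool = True,
    cluster_params: ClusterParams = ClusterParams(),
    seed: SeedLike = 0,
    orf_length: int = 300,
    min_overlap: float = 0.9,
    plant: bool = True,
) -> BenchmarkResult:
    """Run the full scan+call pipeline over generated transcripts.

    Recall counts a planted cluster as recovered when some called cluster
    covers at least ``min_overlap`` of the planted span; precision is the
    fraction of called clusters that recover a planted span.  For each
    IUPAC-pattern box the table compares the mean count of background hits
    (hits disjoint from every planted region) per transcript against the
    analytic per-window expectation on uniform-composition background, with a
    z-score using the Monte-Carlo standard error.  Seed-reproducible.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    defs = default_box_set()
    iupac_defs = [d for d in defs if d.kind == "iupac_pattern"]
    master = np.random.default_rng(seed)
    plan_seed, tr_seed = (int(s) for s in master.integers(2**31, size=2))

    n_planted = n_recovered = n_called = n_matched_calls = 0
    bg_counts: dict[str, list[int]] = {d.name: [] for d in iupac_defs}
    expected: dict[str, float] = {}
    for t in range(n_transcripts):
        if plant:
            plan = make_default_plan(
                utr_length=utr_length,
                background_gc=background_gc,
                exact_consensus=exact_consensus,
                seed=[plan_seed, t],
            )
        else:
            plan = PlantPlan(
                utr_side="five_prime",
                planted_boxes=(),
                utr_length=utr_length,
                background_gc=background_gc,
            )
        record, truth = synth_transcript(
            plan, orf_length=orf_length, seed=[tr_seed, t], record_id=f"t{t}"
        )
        utr_text = record.sequence[: plan.utr_length]
        hits = scan_boxes(utr_text, defs)
        calls = call_clusters(hits, cluster_params)
        planted_regions = [h.region for h in truth.planted_hits]
        if truth.expected_cluster_span is not None:
            n_planted += 1
            span = Region(*truth.expected_cluster_span)
            matched = [
                c
                for c in calls
                if c.region.intersection_length(span) >= min_overlap * len(span)
            ]
            if matched:
                n_recovered += 1
            n_matched_calls += len(matched)
        n_called += len(calls)
        for d in iupac_defs:
            n_bg = sum(
                1
                for h in hits
                if h.box_name == d.name
                and not any(h.region.overlaps(p) for p in planted_regions)
            )
            bg_counts[d.name].append(n_bg)
            if d.name not in expected:
                L = len(d.pattern)
                n_windows = sum(
                    1
                    for i in range(plan.utr_length - L + 1)
                    if not any(
                        Region(i, i + L).overlaps(p) for p in planted_regions
                    )
                )
                expected[d.name] = n_windows * expected_hit_density(
                    d, gc=background_gc
                )

    rows = []
    for d in iupac_defs:
        obs = np.array(bg_counts[d.name], dtype=float)
        exp = expected[d.name]
        # Monte-Carlo SE of the mean count under the analytic window model
        # (per-window hit-count variance x number of windows); the empirical
        # SE is unstable for the sparse alpha-box counts
        n_windows = exp / expected_hit_density(d, gc=background_gc)
        var_transcript = n_windows * hit_count_variance(d, gc=background_gc)
        se = np.sqrt(var_transcript / len(obs))
        z = (obs.mean() - exp) / se if se > 0 else np.nan
        rows.append(
            {
                "box": d.name,
                "pattern": d.pattern,
                "mean_background_hits": obs.mean(),
                "expected_background_hits": exp,
                "observed_sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
                "mc_se": se,
                "z": z,
            }
        )
    recall = n_recovered / n_planted if n_planted else float("nan")
    precision = n_matched_calls / n_called if n_called else float("nan")
    return BenchmarkResult(
        recall=recall,
        precision=precision,
        n_planted=n_planted,
        n_recovered=n_recovered,
        n_called=n_called,
        n_transcripts=n_transcripts,
        box_stats=pd.DataFrame(rows),
    )


# --- the "paper-five" preset -------------------------------------------------
#
# Five synthetic genes emulating the five published arthropod SOPE-bearing
# loci: box composition, cluster span and ORF-relative placement follow the
# printed per-species descriptions (D. melanogaster 297 bp ending 144 bp
# upstream of the start codon in a 560-bp 5' UTR; T. castaneum 247 bp ending
# 95 bp upstream; D. pulex 882 bp ending 1,048 bp upstream; C. salei 3-249 bp
# downstream of the stop codon in the 3' UTR; S. maritima 36-601 bp upstream),
# and the protein parameters follow the printed identities (Ase proteins at
# 50%, CsASH2 at ~30% without the Ase motif, Sm ASH at 62%).

_BOX_WIDTHS = {"E": 6, "alpha": 9, "beta": 8, "N": 6}

PAPER_FIVE_SPECIES = (
    # id, utr_side, utr_len, box order, cluster start, cluster end, k, motif
    ("Dm_ase", "five_prime", 560,
     ("E", "E", "alpha", "beta", "alpha", "E", "N", "E"), 119, 416, 8, True),
    ("Tc_ase", "five_prime", 1300,
     ("E", "beta", "alpha", "beta", "E", "beta", "N", "beta", "alpha", "E", "beta"),
     958, 1205, 8, True),
    ("Dp_ase", "five_prime", 2000,
     ("E", "beta", "alpha", "N", "beta"), 70, 952, 8, True),
    ("Cs_ASH2", "three_prime", 400,
     ("E", "alpha", "E", "beta", "E"), 3, 249, 4, False),
    ("Sm_ASH", "five_prime", 700,
     ("E", "alpha", "beta", "E", "beta", "alpha", "beta", "E", "N", "beta",
      "alpha", "E", "beta"), 99, 664, 10, False),
)


def _layout_boxes(
    order: Sequence[str], span_start: int, span_end: int, rng: np.random.Generator
) -> tuple:
    """Place boxes across [span_start, span_end) with near-equal gaps; the
    first box starts at span_start and the last ends at span_end."""
    widths = [_BOX_WIDTHS[name] for name in order]
    total = sum(widths)
    span = span_end - span_start
    if span < total:
        raise ValueError("span too small for the requested boxes")
    n = len(order)
    gap = (span - total) / (n - 1) if n > 1 else 0.0
    defs = {d.name: d for d in default_box_set()}
    boxes = []
    pos = float(span_start)
    seen_e = False
    for i, (name, w) in enumerate(zip(order, widths)):
        off = span_end - w if i == n - 1 else int(round(pos))
        if name == "E" and not seen_e:
            text = "CAGCTG"  # the full logo appears exactly once per species
            seen_e = True
        else:
            text = draw_box_instance(defs[name], rng)
            while name == "E" and text == "CAGCTG":
                text = draw_box_instance(defs[name], rng)
        boxes.append((name, off, text))
        pos = off + w + gap
    return tuple(boxes)


def paper_five_bundle(seed: SeedLike = 0, orf_length: int = 300) -> dict:
    """Generate the five-gene synthetic preset with ground truth.

    Returns a dict with ``transcripts`` and ``proteins`` (record lists),
    ``pairing`` (protein id -> transcript id), ``orf_table`` (transcript id ->
    (start, end)), and ``truths`` (record id -> SyntheticTruth).
    """
    master = np.random.default_rng(seed)
    sub = [int(s) for s in master.integers(2**31, size=2 * len(PAPER_FIVE_SPECIES))]
    transcripts, proteins = [], []
    pairing, orf_table, truths = {}, {}, {}
    for i, (gene, side, utr_len, order, cs, ce, k, motif) in enumerate(
        PAPER_FIVE_SPECIES
    ):
        rng = np.random.default_rng([sub[2 * i], 0])
        boxes = _layout_boxes(order, cs, ce, rng)
        plan = PlantPlan(
            utr_side=side, planted_boxes=boxes, utr_length=utr_len
        )
        t_id, p_id = f"{gene}_transcript", f"{gene}_protein"
        record, truth = synth_transcript(
            plan, orf_length=orf_length, seed=[sub[2 * i], 1], record_id=t_id
        )
        transcripts.append(record)
        truths[t_id] = truth
        orf_table[t_id] = (truth.orf.start, truth.orf.end)
        label = _expected_label(k, motif)
        prec, ptruth = synth_protein(
            label, k, motif, length=250, seed=[sub[2 * i + 1], 0], record_id=p_id
        )
        proteins.append(prec)
        truths[p_id] = ptruth
        pairing[p_id] = t_id
    return {
        "transcripts": transcripts,
        "proteins": proteins,
        "pairing": pairing,
        "orf_table": orf_table,
        "truths": truths,
    }
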