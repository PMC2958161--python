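"""Diagnostic protein motifs of the achaete-scute family.

Two measurements separate proneural ASH proteins from precursor-specific
Ase proteins:

1. **C-terminal domain identity** — ungapped identity of the best 16-residue
   window in the protein's tail against the reference ASH C-terminal domain
   ``PDDEELLDYISWWQQQ``.  ASH proteins conserve it well; Ase proteins show
   50 % identity or less.
2. **Ase motif** — a five-residue pattern, hydrophobic–Lys–polar–Glu–
   hydrophobic, present in Ase proteins and absent from non-dipteran ASH
   proteins.

The classification rule is: any Ase-motif hit → ``ase``; else C-terminal
identity at or above the threshold (default 0.5) → ``ASH``; else
``indeterminate``.  The presence of a SOPE in the transcript UTR is then
integrated as a second, regulatory line of evidence at the gene level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seq_io import Region
from .sope_caller import SopeCall

ASH_CTERM_REFERENCE = "PDDEELLDYISWWQQQ"

# Standard biochemical groupings; the field names classes without fixing
# membership, so both sets are configuration-overridable.  Y and C sit in both.
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWYC")
DEFAULT_POLAR = frozenset("STNQYCGH")

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AaClassConfig:
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC
    polar: frozenset = DEFAULT_POLAR

    def __post_init__(self) -> None:
        for name, s in (("hydrophobic", self.hydrophobic), ("polar", self.polar)):
            if not s:
                raise ValueError(f"{name} class must be non-empty")
            bad = set(s) - _AA
            if bad:
                raise ValueError(f"{name} class contains non-amino-acid codes {bad}")


@dataclass(frozen=True)
class DomainMatch:
    """Best ungapped 16-mer alignment to the C-terminal reference."""

    window: Region
    identity: float
    n_identical: int
    aligned_pair: tuple  # (reference, matched 16-mer)

    @property
    def display_percent(self) -> int:
        """Identity as a whole percent, truncated toward zero (10/16 -> 62)."""
        n = len(self.aligned_pair[0])
        return self.n_identical * 100 // n


@dataclass(frozen=True)
class ProteinEvidence:
    cterm: Optional[DomainMatch]
    ase_motif_hits: tuple
    label: str  # ASH | ase | indeterminate


@dataclass(frozen=True)
class GeneClassification:
    gene_label: str  # proneural_ASH | ase_like | ancestral_ASH_ase_like | indeterminate
    protein_evidence: ProteinEvidence
    sope_evidence: Optional[SopeCall]


def cterm_identity(
    protein: str,
    reference: str = ASH_CTERM_REFERENCE,
    search_tail: int = 40,
) -> Optional[DomainMatch]:
    """Best ungapped identity of a C-terminal window against the reference.

    Every window of the reference's length lying entirely within the final
    ``search_tail`` residues is compared position-by-position; the window with
    maximal identity is returned, ties broken toward the C-terminus.  Proteins
    shorter than the reference yield ``None`` (absent, with the caller free to
    report why).
    """
    protein = protein.upper()
    L = len(reference)
    if len(protein) < L:
        return None
    lo = max(0, len(protein) - search_tail)
    best: Optional[tuple[int, int]] = None  # (n_identical, start)
    for start in range(lo, len(protein) - L + 1):
        window = protein[start : start + L]
        n_id = sum(1 for a, b in zip(reference, window) if a == b)
        if best is None or (n_id, start) >= best:
            best = (n_id, start)
    n_id, start = best
    return DomainMatch(
        window=Region(start, start + L),
        identity=n_id / L,
        n_identical=n_id,
        aligned_pair=(reference, protein[start : start + L]),
    )


def find_ase_motif(
    protein: str, classes: AaClassConfig = AaClassConfig()
) -> list[int]:
    """All 0-based start positions of hydrophobic-K-polar-E-hydrophobic windows."""
    protein = protein.upper()
    hits = []
    for i in range(len(protein) - 4):
        w = protein[i : i + 5]
        if (
            w[0] in classes.hydrophobic
            and w[1] == "K"
            and w[2] in classes.polar
            and w[3] == "E"
            and w[4] in classes.hydrophobic
        ):
            hits.append(i)
    return hits


def classify_protein(
    cterm: Optional[DomainMatch],
    motif_hits: Sequence[int],
    cterm_min: float = 0.5,
) -> str:
    """ase if any Ase-motif hit; else ASH if C-terminal identity >= threshold;
    else indeterminate."""
    if motif_hits:
        return "ase"
    if cterm is not None and cterm.identity >= cterm_min:
        return "ASH"
    return "indeterminate"


def measure_protein(
    protein: str,
    reference: str = ASH_CTERM_REFERENCE,
    search_tail: int = 40,
    classes: AaClassConfig = AaClassConfig(),
    cterm_min: float = 0.5,
) -> ProteinEvidence:
    """Convenience: run both measurements and classify."""
    cterm = cterm_identity(protein, reference=reference, search_tail=search_tail)
    motif = tuple(find_ase_motif(protein, classes=classes))
    return ProteinEvidence(
        cterm=cterm, ase_motif_hits=motif, label=classify_protein(cterm, motif, cterm_min)
    )


def integrate_gene_call(
    protein_evidence: ProteinEvidence,
    sope: Optional[SopeCall],
) -> GeneClassification:
    """Join protein and regulatory (SOPE-in-UTR) evidence into a gene label.

    A UTR SOPE marks the gene as precursor-specific (ase-like) regardless of
    the protein call — except for a clear ASH protein, where the combination
    is read as the ancestral, unduplicated ASH/ase state (the myriapod
    condition).  Without a SOPE the protein evidence stands alone.
    """
    p = protein_evidence.label
    if sope is not None:
        label = "ancestral_ASH_ase_like" if p == "ASH" else "ase_like"
    else:
        label = {"ASH": "proneural_ASH", "ase": "ase_like"}.get(p, "indeterminate")
    return GeneClassification(
        gene_label=label, protein_evidence=protein_evidence, sope_evidence=sope
    )
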