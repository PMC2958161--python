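"""Position-frequency matrices, information content, consensus calls, and a
permutation test for conservation of motif-flanking nucleotides.

Aligned box instances are summarised as a position frequency matrix (PFM).
Per-column information content follows the sequence-logo convention,
``IC_i = 2 − H_i`` bits with ``H_i`` the Shannon entropy of the column's base
frequencies; the optional small-sample correction subtracts
``e(n) = 3 / (2 ln2 · n)`` and floors at zero.  The correction defaults off
because the site sets pooled here are small (5–17 sites) and either variant
may be wanted.

Whether the residual context around a motif is conserved is made operational
by a permutation test: the statistic is the mean IC over the flank columns,
and the null is built by pooling all flank letters (across sites and flank
columns) and redistributing them uniformly, ``n_perm`` times, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Optional, Sequence, Union

import numpy as np

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_LN2 = log(2.0)

# minimal IUPAC code covering each non-empty base subset
_IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class SiteAlignment:
    """Equal-length aligned instances of one box class, with optional flanks.

    Site length = core width + 2 * flank_len; the flank columns are the first
    and last ``flank_len`` positions.
    """

    box_name: str
    sites: tuple
    flank_len: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(s.upper() for s in self.sites))
        if not self.sites:
            raise ValueError("alignment requires at least one site")
        L = len(self.sites[0])
        if any(len(s) != L for s in self.sites):
            raise ValueError("all sites must have equal length")
        if self.flank_len < 0 or 2 * self.flank_len > L:
            raise ValueError("flank_len inconsistent with site length")

    @property
    def width(self) -> int:
        return len(self.sites[0])


@dataclass(frozen=True)
class Pfm:
    """Per-column base counts and frequencies over unambiguous sites."""

    counts: np.ndarray  # shape (4, width), rows A,C,G,T
    n_sites: int
    n_excluded: int = 0

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sites


@dataclass(frozen=True)
class LogoTrack:
    ic: np.ndarray  # bits per column, in [0, 2]
    consensus: str
    correction_applied: bool


class InsufficientSitesError(ValueError):
    """Flank test asked for with fewer usable sites than the test requires."""


@dataclass(frozen=True)
class FlankTestResult:
    observed_mean_ic: float
    p_value: float
    n_perm: int
    n_sites_used: int
    n_flank_columns: int


def _encode(sites: Sequence[str]) -> tuple[np.ndarray, int]:
    """Integer-encode sites, dropping any containing a non-ACGT letter.

    Returns (matrix of shape (n_kept, width), n_excluded)."""
    kept = []
    excluded = 0
    for s in sites:
        if all(c in _BASE_INDEX for c in s):
            kept.append([_BASE_INDEX[c] for c in s])
        else:
            excluded += 1
    return np.array(kept, dtype=np.int8).reshape(len(kept), -1), excluded


def build_pfm(alignment: SiteAlignment) -> Pfm:
    """Column-wise base counts over the alignment's unambiguous sites."""
    mat, excluded = _encode(alignment.sites)
    if mat.shape[0] == 0:
        raise ValueError("no unambiguous sites to tally")
    width = alignment.width
    counts = np.zeros((4, width), dtype=np.int64)
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    return Pfm(counts=counts, n_sites=mat.shape[0], n_excluded=excluded)


def _column_entropy(freq: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits per column; freq shape (..., 4, width)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(freq), 0.0)
    return -terms.sum(axis=-2)


def information_content(
    pfm: Pfm, small_sample_correction: bool = False
) -> LogoTrack:
    """Per-column IC in bits and the consensus string for a PFM."""
    ic = 2.0 - _column_entropy(pfm.frequencies)
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * _LN2 * pfm.n_sites)
    ic = np.clip(ic, 0.0, 2.0)
    consensus = _consensus(pfm.frequencies, ic)
    return LogoTrack(ic=ic, consensus=consensus, correction_applied=small_sample_correction)


def _consensus(freq: np.ndarray, ic: np.ndarray) -> str:
    letters = []
    for col in range(freq.shape[1]):
        f = freq[:, col]
        top = int(np.argmax(f))
        if f[top] >= 0.75 and ic[col] >= 1.0:
            letters.append(_BASES[top])
            continue
        included = frozenset(_BASES[b] for b in range(4) if f[b] >= 0.25)
        letters.append(_IUPAC_FROM_SET.get(included, "N"))
    return "".join(letters)


def consensus_from_pfm(pfm: Pfm, small_sample_correction: bool = False) -> str:
    """Deterministic IUPAC consensus under the logo rules.

    A column is written as a single base when that base's frequency is at
    least 0.75 and the column carries at least 1 bit; otherwise as the minimal
    IUPAC code covering all bases at frequency >= 0.25; otherwise N.
    """
    return information_content(pfm, small_sample_correction).consensus


def flank_conservation_test(
    alignment: SiteAlignment,
    n_perm: int = 1000,
    seed: int = 0,
    small_sample_correction: bool = False,
) -> FlankTestResult:
    """Permutation test for conservation of the nucleotides flanking a motif.

    Statistic: mean IC over the flank columns.  Null: each permutation pools
    every flank letter across all flank columns and sites, shuffles the pool,
    and refills the columns; the p-value is ``(1 + #null >= observed) /
    (1 + n_perm)``.  Reproducible bit-for-bit given (alignment, n_perm, seed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alignment.flank_len < 1:
        raise ValueError("alignment has no flank columns")
    mat, _ = _encode(alignment.sites)
    n_sites = mat.shape[0]
    if n_sites < 3:
        raise InsufficientSitesError(
            f"flank test requires >= 3 unambiguous sites, got {n_sites}"
        )
    f = alignment.flank_len
    width = alignment.width
    cols = list(range(f)) + list(range(width - f, width))
    flanks = mat[:, cols]  # (n_sites, n_flank_cols)
    n_cols = flanks.shape[1]

    def mean_ic(columns: np.ndarray) -> np.ndarray:
        # columns: (..., n_sites, n_cols) integer-coded
        counts = np.stack(
            [(columns == b).sum(axis=-2) for b in range(4)], axis=-2
        )  # (..., 4, n_cols)
        freq = counts / n_sites
        ic = 2.0 - _column_entropy(freq)
        if small_sample_correction:
            ic = ic - 3.0 / (2.0 * _LN2 * n_sites)
        ic = np.clip(ic, 0.0, 2.0)
        return ic.mean(axis=-1)

    observed = float(mean_ic(flanks))
    rng = np.random.default_rng(seed)
    pool = flanks.reshape(-1)
    tiled = np.tile(pool, (n_perm, 1))
    shuffled = rng.permuted(tiled, axis=1).reshape(n_perm, n_sites, n_cols)
    null = mean_ic(shuffled)
    p = (1.0 + int((null >= observed - 1e-12).sum())) / (1.0 + n_perm)
    return FlankTestResult(
        observed_mean_ic=observed,
        p_value=p,
        n_perm=n_perm,
        n_sites_used=n_sites,
        n_flank_columns=n_cols,
    )


def sites_from_hits(
    sequence: str,
    hits: Sequence,
    flank_len: int = 0,
    orient: bool = True,
) -> list[str]:
    """Extract aligned site texts (with flanks) for a set of same-width hits.

    Minus-strand hits are reverse-complemented when ``orient`` is set so all
    sites read in motif orientation.  Hits whose flanks would run off the
    sequence are skipped.
    """
    from .box_models import reverse_complement

    out = []
    for h in hits:
        s = h.region.start - flank_len
        e = h.region.end + flank_len
        if s < 0 or e > len(sequence):
            continue
        text = sequence[s:e].upper()
        if orient and h.strand == "-":
            text = reverse_complement(text)
        out.append(text)
    return out


def logo_table(pfm: Pfm, track: LogoTrack):
    """Logo track as a tidy DataFrame: column, A/C/G/T frequency, IC, consensus."""
    import pandas as pd

    freq = pfm.frequencies
    return pd.DataFrame(
        {
            "column": np.arange(1, pfm.width + 1),
            "A": freq[0],
            "C": freq[1],
            "G": freq[2],
            "T": freq[3],
            "ic_bits": track.ic,
            "consensus": list(track.consensus),
        }
    )


def plot_logo(pfm: Pfm, track: LogoTrack, path) -> None:
    """Render a simple stacked-bar logo (IC-scaled letter heights) to a file.

    Requires matplotlib (the ``plot`` extra); statistics never depend on it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = pfm.frequencies
    heights = freq * track.ic  # (4, width)
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(3, pfm.width * 0.5), 2.5))
    for col in range(pfm.width):
        bottom = 0.0
        order = np.argsort(heights[:, col])
        for b in order:
            h = heights[b, col]
            if h <= 0:
                continue
            ax.bar(col + 1, h, bottom=bottom, color=colors[_BASES[b]], width=0.8)
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_title(f"n = {pfm.n_sites} sites; consensus {track.consensus}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
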