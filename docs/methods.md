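# Methods

## Coordinates and sequence handling

All coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive positions. FASTA reading and writing go through Biopython;
identifiers are the first whitespace-delimited token of the header and
sequences are upper-cased on ingest. Nucleotide records accept the full IUPAC
alphabet; anything else is a parse error naming the record and position.

ORF inference considers the forward strand only — inputs are transcripts,
not genomic contigs. The inferred ORF is the longest `ATG`…first-in-frame
stop (`TAA`/`TAG`/`TGA`, stop included), ties broken toward the smallest
start. Codons containing ambiguity codes are never accepted as start or
stop, so draft-genome N runs cannot fabricate ORF boundaries. Caller-supplied
ORF coordinates (e.g. from gene models) are validated and passed through
verbatim; both routes are exposed because published UTR boundaries are
sometimes model-derived and sometimes ORF-derived. UTRs are the complement
of the ORF within the transcript: `[0, orf.start)` and `[orf.end, length)`.

## Box models and scanning

The four binding-site classes default to canonical literature consensus
sequences — E = `CANNTG`, N = `CACNAG`, α = `GGGWWWNCC`, β = AT-rich window
(width 8, ≥ 0.85 A/T) — and all four are configuration-overridable, because
the curated site alignments behind the published logos are not recoverable
from text; the α-box width in particular (9 vs 10) is undetermined.

Matching uses the IUPAC **subset rule**: window letter set ⊆ pattern letter
set at every position. Under this rule an `N` in the scanned sequence
matches only an `N`-compatible pattern position; a `wildcard` policy flag
relaxes this to set intersection. The strict default avoids spurious boxes
inside assembly-gap N runs.

IUPAC patterns are scanned at every window on both strands; minus-strand
hits are reported in forward coordinates with the forward-strand slice as
`matched_text`. A locus whose matched site is its own reverse complement is
reported once with strand `+` (palindrome deduplication); a degenerate
pattern matching a non-palindromic site on both strands yields two hits.
Note the E box is self-complementary as a *pattern*: every forward `CANNTG`
match also matches in reverse, so non-palindromic E sites always produce a
+/− hit pair. Overlapping hits are all reported — deciding relevance is the
cluster caller's job.

The β scanner slides a width-8 window, marks windows at ≥ 85 % A/T, merges
overlapping or adjacent qualifying windows, and trims each merged region to
its outermost A/T bases before reporting it as one strandless hit. The trim
step keeps a single flanking G/C (dragged in by a 7/8 window) from padding
the reported element.

Analytic companions: the per-window match probability of a pattern on
i.i.d. DNA of given GC content, the both-strand expected hit density
(`p_fwd + p_rev − p_palindromic`), and the per-window hit-count variance.
The variance accounts for the 2-hit outcome of both-strand matches, which
makes E-box counts markedly over-dispersed relative to Poisson; z-scores for
background calibration use this model-based Monte-Carlo standard error
rather than the empirical one, which is unstable for the sparse α-box
counts.

## Cluster calling and localisation

Clusters are built by single-linkage chaining over start-sorted hits: a hit
joins the current chain when the gap between the chain's rightmost end and
the hit's start is ≤ `gap_max`. Chains failing `min_boxes` or `min_types`
are discarded. Defaults — gap ≤ 450 bp, ≥ 4 boxes, ≥ 3 distinct classes —
were chosen so that all five published arthropod SOPEs (5–13 boxes of 3–4
classes over 246–1,052 bp) pass while isolated hits do not. A merged β
region counts as one box. Chaining guarantees maximal, non-overlapping
clusters, monotone in `gap_max`.

Localisation uses the **gap convention**: distances count the bases strictly
between the cluster and the codon. A cluster wholly 5' of the ORF reports
`upstream_distance = orf.start − cluster.end`; wholly 3' reports
`downstream_near/far = cluster.start/end − orf.end`; anything else is
`overlapping_orf`. This reproduces the field's phrasing exactly: a cluster
`[10, 156)` with ORF start 300 is "144 bp upstream of the start codon", and
`[503, 749)` with ORF end 500 is "between 3 bp and 249 bp downstream of the
stop codon". By default hits are scanned per-UTR (ORF-internal matches
excluded), with a whole-transcript flag.

## Protein features

C-terminal identity is an ungapped position-by-position comparison of every
16-residue window lying within the final 40 residues against the reference
`PDDEELLDYISWWQQQ`, best window returned, ties toward the C-terminus.
Identity is an exact fraction k/16; display percentages truncate toward zero
(10/16 → 62 %), matching how such identities are conventionally printed.
The Ase motif is any 5-mer `[hydrophobic] K [polar] E [hydrophobic]` with
hydrophobic = {A,V,L,I,M,F,W,Y,C} and polar = {S,T,N,Q,Y,C,G,H} — standard
biochemical groupings, configurable because the class memberships are a
convention, not a measurement; Y and C sit in both sets.

Classification: any Ase-motif hit → `ase`; else C-terminal identity ≥ 0.5 →
`ASH`; else `indeterminate`. The 0.5 threshold operationalises the "50 %
identity or less" boundary that separates Ase-type C-termini from ASH ones.
bHLH-domain detection is deliberately **not** a criterion — the bHLH is how
family members are found, not how ASH and ase are separated.

Gene-level integration: a SOPE in the UTR marks the gene `ase_like`
regardless of a weak or Ase-type protein call; combined with a clear ASH
protein it is read as the ancestral unduplicated state
(`ancestral_ASH_ase_like`, the extant myriapod condition); without a SOPE
the protein evidence stands alone.

## Logos and the flank test

Aligned sites are tallied into a position frequency matrix over unambiguous
(pure-ACGT) sites; ambiguity-containing sites are excluded whole and
counted, keeping integer tallies. Information content is `2 − H` bits per
column; the small-sample correction `e(n) = 3/(2·ln2·n)` (floored at 0) is
available but off by default — the pooled site sets here are small (5–17)
and the published logos' exact recipe is unstated, so both variants are one
flag apart. Consensus per column: a single base when its frequency ≥ 0.75
and the column carries ≥ 1 bit; otherwise the minimal IUPAC code covering
bases at frequency ≥ 0.25; otherwise N. The thresholds are this package's
choice, fixed once: they are deterministic and recover `CAGCTG` when the
full-logo E box from each species is pooled.

Whether motif-flanking nucleotides are conserved is made operational with a
permutation test. Statistic: mean IC over the flank columns. Null: pool all
flank letters across sites *and* flank columns, shuffle, refill — i.e. flank
composition is preserved but any column-specific structure is destroyed.
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`, seeded and bit-for-bit
reproducible. Under i.i.d. flanks the observed statistic is exchangeable
with the permuted ones, so the test is calibrated; ties make it mildly
conservative. Measured type-I rate at α = 0.05 is within 0.05 ± 0.02 over
500 simulated 10-site alignments (199 permutations each, chosen so the
rejection region boundary falls exactly on the 10th order statistic).

## Synthetic data

Generators are pure functions of their arguments, seed included, so every
test condition is reproducible. Backgrounds are i.i.d. DNA at GC = 0.45 —
arthropod UTRs run AT-rich, and an AT-shifted background deliberately
exposes β-box false positives. Transcripts are assembled as
`[5' UTR][ATG + non-stop codons + TAA][3' UTR]` (or the 3'-UTR mirror) with
box instances written at planned offsets; backgrounds that give the
transcript a longer (or equally long, earlier) spurious ORF than the planted
one are rejected and redrawn, up to 100 times, then a hard error.

Planted instances fill pattern degeneracies uniformly (seeded) with an
option to force the full `CAGCTG` logo — mirroring the observation that the
full logo occurs in only a minority of real E boxes, once per species. The
five-gene preset reproduces the published per-species compositions, spans
and ORF-relative placements: 297 bp ending 144 bp upstream (fly, in the
560-bp 5' UTR), 247 bp ending 95 bp upstream (beetle), 882 bp ending
1,048 bp upstream (water flea), 3–249 bp downstream of the stop (spider,
3' UTR), 36–601 bp upstream (centipede). Where the source descriptions
disagree internally (beetle span 1,145 vs 247 bp; centipede 565 vs
1,052 bp), the preset fixes one arrangement (beetle 247, centipede 565) and
the pipeline always reports its own measured spans rather than adjudicating.

Synthetic proteins plant exact evidence: the C-terminal 16-mer matches the
reference at exactly k positions, with mismatches and the 24 residues before
it drawn from amino acids absent from the reference, so no other tail window
can out-score the planted one; when the motif flag is off, lysine is
excluded from the background, making an accidental Ase motif impossible
(position 2 of the motif must be K). Every emitted protein is re-measured
before return and must reproduce (k/16, motif) exactly.

`benchmark_recovery` runs the full scan+call pipeline over generated
transcripts: recall counts a planted cluster as recovered at ≥ 90 % span
overlap (called clusters may extend beyond the plant — background chance
matches legitimately chain onto it); precision is the fraction of called
clusters that recover a plant; per-pattern background hit counts are
compared to the analytic expectation via the model-based z described above.

## What the synthetic conditions do and do not show

Passing on synthetic data shows the machinery is exact (scanner ≡ brute
force, identities exact, determinism byte-level) and calibrated (background
rates match theory, flank test holds its size). It does not show that the
default consensus choices or cluster parameters are optimal for real
genomes: real UTRs have dinucleotide structure, repeats and composition
heterogeneity that i.i.d. backgrounds lack, and real site instances are not
uniform over pattern degeneracies. In particular, canonical `CANNTG` occurs
roughly every ~150 bp by chance on both strands, so called spans on long
UTRs are systematically wider than a curated, hand-picked box set — visible
directly in the five-gene preset output.

## Problem sizes

Default runs use 100 transcripts (600-bp UTRs) for the benchmark, 200
random ≤ 1-kb sequences for the scanner–oracle check, 340 planted proteins
for classification recovery, and 500 alignments × 199 permutations for the
flank-test calibration; all sizes are arguments and scale linearly.
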