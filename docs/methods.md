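# Methods

## Background and scope

Monitoring substrates (SecM, MifM, VemP and relatives) are small secreted
or membrane-inserted proteins whose nascent chain stalls its own ribosome
through interactions in the exit tunnel and at the peptidyl transferase
center (PTC); engagement of the protein-localization machinery releases the
arrest, coupling downstream *secA*/*secDF*/*yidC* expression to
localization capacity.  `arrestscreen` implements the comparative-genomic
side of that biology: discovering candidate uORFs, classifying their
C-terminal arrest motifs, predicting stall sites and measuring the spacer
between the localization signal and the arrest point.  Wet-lab readouts
(in vitro translation, toeprinting, reporter assays) are out of scope; only
their published stall-site rules are encoded.

## Screening model

A candidate must satisfy, in order:

1. be the **nearest** CDS upstream of a *secA*/*secDF*/*yidC* gene in its
   transcription direction, on the same strand (an intervening
   opposite-strand CDS disqualifies operonic adjacency), with an
   intergenic gap of at most `max_intergenic_gap` (default 1000 nt — the
   operon logic itself carries no published distance cap, so this is an
   explicit knob);
2. encode a protein of < 300 residues (exclusive);
3. carry an unknown-function or known-substrate product annotation
   (case-insensitive substring match; the keyword lists are configuration,
   not constants, because annotation vocabularies vary by pipeline);
4. have a predicted N-terminal localization signal; and
5. retain > `min_spacer` (default 30) residues of soluble tail after the
   signal end, with the protein end standing proxy for the conserved-region
   end at filter time.

Target discovery runs in `annotation` mode (product-string matching;
SecD and SecF both map to the secDF class) or `similarity` mode — a
Smith–Waterman stand-in for blastp using BLOSUM62 with gap open 11 /
extend 1, accepting a hit at ≥ 30 % identity over ≥ 50 % query coverage.
An E-value criterion is not reproducible without full BLAST statistics, so
these thresholds are documented as the package's own operating point;
tabular hits from a real BLAST run can be substituted upstream.

## Localization heuristic

Hydropathy is the Kyte–Doolittle scale averaged over a sliding window
(default 19 residues, odd; value reported at the window center; termini
without a full window are omitted).  A run of centers above
`tm_threshold` (default 1.6) seeds a segment, which is then extended
outward over residues that are individually hydrophobic (KD > 0) — the
extension step makes segment boundaries track the underlying hydrophobic
stretch rather than the window geometry, and makes the predictor exactly
position-covariant under hydrophilic N-terminal padding.  The first
segment must start at or before residue `n_region_max_start` (35) and span
at least `min_segment_len` (15) residues.

A small-residue A-x-A-like motif (positions p and p+2 drawn from {A, G,
S}) ending within 8 residues after the first segment marks a cleavable
signal peptide; the signal end is the residue before the inferred cleavage
point (p+2).  Without such a motif the signal is a TM anchor and the
signal end is the last residue of the **first** segment — the multi-TM
case has no published convention for "last residue of the localization
signal", so the first segment is used and recorded here as an assumption.
The built-in heuristic does not infer topology; topology tags pass
through from external predictions only, supplied as a TSV
(protein_id, kind, seg_start, seg_end, cleavage_pos).  This heuristic is a
deliberately simple, fully deterministic component: it reproduces clean
single-signal constructs exactly but is not a re-implementation of
SignalP/TMHMM-class models and will be wrong on subtle real signals
(short h-regions, Tat signals, signal anchors near the length threshold).

## Clustering

Dereplication is exact sequence identity (representative: lexicographically
smallest id).  Similarity is a single all-vs-all pass — Jaccard index of
3-mer sets by default, optional SW identity (identities / aligned columns
of the optimal local alignment) — thresholded (default 0.4) into a graph.
Two partitions are offered: greedy set cover (pick the unassigned node
with the most unassigned neighbors; ties broken by larger total similarity,
then smaller id; the node plus its unassigned neighbors form a cluster)
and connected components, which merges more remote homologs.  At equal
threshold every set-cover cluster lies inside one connected component.
Iterative profile searches are intentionally not reproduced: the
downstream logic needs only a partition, and the package makes no claim of
matching any particular external tool's cluster counts.  C-terminal
conservation profiles right-anchor cluster members at their final residue
and left-pad with gaps instead of computing a multiple alignment, which is
adequate because every motif of interest is C-terminally anchored.

## Motif panel and classification

The query panel consists of literal tetrads with family code RQH
(experimentally demonstrated: RAGP, RAPP, RAPG, RGSP; recovered variants:
LAGP, RADP, RASP, RAPS, RAPA, RAPT, RGPT, RAPQ, RAPE, RGPS, RGPG, RAPC,
RAPD, RAPV, RGPP, HGPP, RSPP, QAPP, HAPP, TGPP, RDGP), the LPPP query
restricted to the last 15 residues, the terminal-anchored motifs NSP,
NAP and DGMK (a trailing stop codon is part of the motif, so they match
only flush with the C-terminus), and KYxIW ('x' matches any residue).
The RAP\* query is read as terminal R-A-P by default — '\*' denotes a stop
codon in the terminal-motif convention — with a panel option to read it as
R-A-P-x instead, since the source convention is ambiguous.  Internal
queries report **all** (including overlapping) matches ending within the
last 30 residues (configurable); when several hits coexist the most
C-terminal one defines the arrest site, generalizing the di-proline rule
(of multiple P-P motifs, only the most C-terminal is considered).

The MifM-like filter computes mean net charge (D, E = −1; K, R = +1;
H = 0) over a 5-residue sliding window and passes a protein iff the
minimum over windows centered in residues 70–100 (clipped to the
sequence; proteins too short to reach the region fail) is < −0.3.  The
integer charge model approximates a pKa-based calculation; at the −0.3 /
5-residue operating point the two agree except for marginal histidine- or
terminus-dominated cases.  The filter is monotone: acidifying any residue
in the region never turns a pass into a fail.

Family assignment groups motif-bearing candidates by (downstream-gene
class, motif code, GTDB order): ≥ 3 members form a family named
`{uA|uDF|uC}_{code}_{order}`; 1–2 members are orphans.  The output depends
only on the multiset of those triples, so it is permutation-invariant.

## Stall sites and distance_LS

* Elongation arrest (4-residue motifs): P-site = motif start + 2 (the
  tetrad's third residue); defined only for tetrads.
* Termination arrest (terminal motifs): the stop codon occupies the
  A-site, so the P-site is the final residue (A-site index = length + 1).
* Override families (KYxIW): the conserved motif sits upstream of the
  stall point, so the P-site comes from a per-family offset table
  (default: 6 residues past the motif's last residue, the strongest
  observed toeprint; minor secondary sites are not modeled).

Derived geometry: `relative_cterm_position(L, i) = i − L − 1` (final
residue ↦ −1) and `ptc_separation(p, i) = (p + 1) − i` (the P-site residue
is 1 from the PTC).  `distance_LS` is P-site minus signal end and must be
positive; criterion-5 filtering uses the soluble-tail spacer
(protein end − signal end) instead, and the two are kept as distinct
columns because they answer different questions.

Cohort spacer distributions are summarized by the median plus a modality
split: a Gaussian KDE with Silverman bandwidth is evaluated on a 512-point
grid padded 5 % beyond the data range, and the cohort is split at the
valley only when the density shows exactly two interior maxima separated
by one interior minimum.  This formalizes what is otherwise a by-eye call
on a raincloud plot; `--split none` and `--split threshold:<v>` override
it.  Degenerate inputs (constant values) yield a single group.

## Synthetic cohort

The generator emulates the screening substrate: one contig per genome,
planted uORF–target operons (configurable downstream class, motif, signal
kind, spacer, intergenic gap, product string, strand), informative decoy
genes, and two negative-control layouts (an informatively annotated
upstream gene; an opposite-strand upstream gene).  Construction choices
that make ground truth exact: signal regions are clean hydrophobic cores
(L/I/V/F) flanked by a neutral alphabet (T/N/Q/H/Y) that can seed neither
a panel motif, a cleavage motif, a charged window nor a TM segment;
signal-peptide constructs end in a Q-A-H-A c-region so the predicted
cleavage point is unambiguous.  Unspecified spacers are drawn from an
integer-rounded normal mixture (defaults: modes 70 ± 5 and 130 ± 5, equal
weight, floor 40) so modality-split recovery is testable.  Coding
sequences use uniformly drawn synonymous codons (table 11, fixed ATG
start, TAA stop); everything is driven by one seeded generator, so output
files are byte-identical across runs.  At generation time every planted
uORF is re-translated, re-predicted and re-scanned, and generation fails
if the manifest would not be self-consistent.

The default 20-genome cohort plants five families (RGPP upstream of
*secA* ×4 and of *secDF* ×3, KYxIW ×3, terminal-NSP ×3, LPPP ×3), one
two-member orphan group (QAPP) and two negative controls, spread over six
orders and phyla so both the ≥ 3-per-order family rule and the orphan path
are exercised.  What passing on this cohort does **not** show: robustness
to diverged family members, ambiguous or fused signals, overlapping genes,
annotation noise, or realistic base composition — the generator's
non-goals.

## Problem sizes and numerical notes

Tests and the acceptance script run on the 20-genome default cohort,
1,000-protein scan oracles, ≤ 12-node clustering oracles and 100-value
spacer cohorts — sizes chosen so the whole suite completes in seconds on
one CPU while still exercising every rule at its boundaries.  All
coordinates are 1-based inclusive end-to-end; similarity and frequency
invariants are enforced to 1e−9; ambiguous bases translate to X and such
candidates are kept but visible in the table; tie-breaks everywhere are
deterministic (lexicographic) so every pipeline stage is input-order
invariant and reruns are bit-identical.
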