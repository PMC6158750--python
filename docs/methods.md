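# Methods

## Model and assumptions

`cleaveseek` predicts sRNA targets from two kinds of evidence: sequence
complementarity between a sRNA and a transcript site, and a degradome tag
whose 5′ end marks the cleavage position at that site. The model assumes
plant-style RISC cleavage between the target bases opposite sRNA positions
10 and 11, degradome tags that derive from the 3′ cleavage fragment (so
tags are matched to the transcript sense strand only, exactly, with no
mismatches), and adapter-trimmed input reads. Antisense tag matching,
mismatch-tolerant tag alignment and probabilistic multi-mapping resolution
are deliberately out of scope; a multi-mapping tag is reported at every
position it matches, with its abundance divided evenly among them
("weighted abundance").

## Coordinate conventions

All coordinates are 1-based. A tag 5′ end at transcript position p defines
cleavage position p, paired with sRNA position 10. The candidate window
spans transcript positions p−16 … p+15 (length 32, p at window position
17); gap-free, sRNA position i pairs window position 27−i. Candidates
within 16 nt of the 5′ end or 15 nt of the 3′ end of a transcript are not
generated. sRNA regions: R1 = positions 1–7, R2 = 8–14, R3 = the last
seven bases (overlapping R2 for sRNAs shorter than 21 nt). Target regions
TR1/TR2/TR3 are the window bases opposite those positions, read 3′→5′
along the transcript and encoded in mRNA mode, so a perfectly
complementary region pair shares one integer.

## Region prefiltering and its conservativeness contract

Conceptually each region has a 16384×16384 boolean matrix over (sRNA
7-mer, mRNA 7-mer) codes marking pairs that can appear inside some
rule-compliant duplex. Materializing three such matrices costs ≈0.8 GB;
instead rows (and individual cells) are computed lazily and memoized, only
for region codes actually present in the data. Identical results, desk
memory.

A cell is declared valid by an existential search over gap-free and
small-gap region alignments: the start offset (|offset| ≤ max_gaps) models
gaps elsewhere in the duplex shifting the reading frame through the
region; bases shifted outside the 7-mer and gap columns themselves are
free (their cost may fall outside the region); budgets are the full global
budgets, never a partition. Each of these choices makes the region test
strictly weaker than the full duplex aligner, which yields the key
contract: filtering never removes a candidate the duplex aligner would
accept, so predictions with filtering on equal predictions with filtering
bypassed. The suite verifies this over 1000 random fixtures under both
presets and gap budgets 0 and 1. The price is weaker pruning, which only
costs time, never results.

## Duplex alignment

The aligner anchors sRNA position 10 opposite window position 17 — the
anchor pair is never gapped — and walks outward, 5′ arm first, branching
on single-base bulges in either strand up to `max_gaps`. Scoring: mismatch
`mismatch_score`, G:U wobble `gu_wobble_score`, bulge `gap_score`, each
multiplied by `core_multiplier` when the sRNA position being traversed
lies in [core_start, core_end]. A bulged window base is charged at the
position the arm is traversing and is treated as outside the core region
for core-count purposes. Position-10/11 prohibitions cover both mismatches
and wobbles. Gap columns always count as mismatch-like for the adjacency
rule; wobbles only when `gu_counts_as_mismatch` is set (the switch also
adds wobbles to the mismatch count). Branches are pruned on score and
count budgets in flight; adjacency and core counts are checked on each
completed alignment.

All surviving alignments are collected and the reported one is the
lexicographic minimum of (score, gaps, mismatches + wobbles), with any
remaining tie broken by the 5′-most first difference in column states
(match < wobble < mismatch < sRNA-gap < target-gap) — fully deterministic.

Presets: `allen` (mismatch 1.0, G:U 0.5, gap 1.0, core 2–13 ×2, max score
4.0, ≤4 mismatches, ≤2 adjacent, ≤1 gap, no mismatch/wobble at 10–11) and
`fahlgren_carrington`, identical except positions 10 and 11 are permitted
(at the plain mismatch score). Core-region count maxima default to the
global maxima and the wobble cap defaults high (8) so that, as in the
classic schemes, the score cutoff is what binds. Every field round-trips
through a flat JSON configuration file.

## Peak categories and the binomial p-value

Categories follow the five-way degradome convention — unique maximum (0),
tied maximum (1), above average (2), at/below average (3), singleton (4) —
with the average taken only over positions with abundance > 1, so that
ubiquitous abundance-1 background does not depress it. The p-value for a
site of category c on a transcript is p = 1 − (1 − q_c)^n, where q_c is
the fraction of the transcript's signal positions with category ≤ c and n
is the number of candidate positions on that transcript evaluated for the
querying sRNA *after* region filtering. It answers: how likely is it that
at least one of the evaluated positions would carry an equal-or-better
signal by chance? The per-transcript formulation (rather than a
transcriptome-wide null) is a design choice; because n counts post-filter
positions, bypassing the region filter changes p-values (but never the
interaction set). The filter is optional and off by default; the MFE-ratio
filter defaults to 0.7, and both cutoffs keep boundary values (a
prediction exactly at the cutoff passes).

## Energy backend

The default backend is a bundled nearest-neighbor stack-energy table
(version `builtin-nn-1.0`): Turner-style free energies for
Watson–Crick/Watson–Crick stacks, a milder constant (−1.2 kcal/mol) for
stacks involving G:U, destabilizing penalties for mismatches (+0.5) and
bulges (+3.0), duplex initiation +4.09 and terminal A:U/G:U penalties
+0.45. It is not intended to reproduce any external folding engine to the
decimal; it is deterministic, shipped with the package, strictly negative
on perfect duplexes ≥19 nt, and strictly destabilized by every
mismatch — which is all the MFE *ratio* filter needs, since the ratio
normalizes by the perfect-site energy of the same sRNA. When the
ViennaRNA python bindings are installed, `--energy-backend vienna`
delegates to `RNA.duplexfold`; the backend in use is part of the run
configuration.

## Input filters

Ambiguous-base removal; low-complexity removal discarding sequences whose
most frequent mono-, di- or tri-nucleotide exceeds 75%, 37.5% or 25% of
the L−k+1 overlapping windows (strict boundaries, measured empirically in
the acceptance script). Under overlapping counting the mono rule is
formally dominated by the di rule — any sequence above 75% of one base
necessarily exceeds 37.5% homo-dimers — so the mono boundary is measured
on the rule in isolation. Conservation filtering intersects sRNA
sequences across replicate libraries (opt-in); genome matching keeps
sRNAs with at least one exact full-length match on either genome strand.
Defaults: sRNA length 19–24 nt, minimum sRNA abundance 5, degradome tag
length 19–21 nt. Normalized abundances are reads-per-million over the
retained (post-filter) library total, logged with each run.

## Synthetic data generator

`cleaveseek.synthgen` emulates the structure of a plant degradome
experiment: uniform-random transcripts (GC 0.5); planted sites whose sRNA
is the reverse complement of the (edited) site; degradome tags of
controlled abundance (default 10, tag length 20 nt) with 5′ ends exactly
at the cleavage position; Poisson background tags of abundance 1, which
are category 4 by construction and hence separable under stringent
settings. Edit specs plant mismatches, wobbles and single bulges at named
sRNA positions; the generator computes each site's expected category and
alignment score from its own bookkeeping, independently of the prediction
modules, and refuses edit specs that violate the named preset. A bulge
flanked by a G and a T cannot be planted (every base would pair with a
neighbour) and such sRNAs are resampled. One integer seed drives all
randomness.

What passing the planted-truth tests shows — and does not show: recovery
of every compatible planted site demonstrates the pipeline's bookkeeping,
geometry and rule logic end to end, but the generator has uniform base
composition, no sequencing errors, no ligation bias, no isoform ambiguity
and no secondary-structure effects, so these tests say nothing about
sensitivity/precision on real libraries.

## Problem sizes and numerical choices

The test suite runs the oracle-agreement checks on 500 random sRNA/window
pairs per preset, conservativeness on 1000 fixtures, and planted-truth
recovery on 100 sites over 40 transcripts of 600–1200 nt; the acceptance
script uses the same 100-site configuration with background rate 2 per
transcript. These sizes exercise every code path (both presets, all edit
classes, gap budgets 0–1) while keeping the full suite in well under a
minute of alignment work. Scores are exact floats built from sums of
0.5-granular penalties; comparisons use exact equality except where noted.
Ties everywhere are broken deterministically, and the prediction path
contains no randomness, so repeated runs are byte-identical.

## Known limitations

- Region coordinates and the exact placement of the cleavage position
  inside the 32-nt window follow the internally consistent convention
  above; tools with a different window convention will report positions
  shifted by a constant.
- The binomial p-value is one reasonable per-transcript formulation;
  other degradome tools parameterize their null differently, so p-values
  are comparable within a run, not across tools.
- The builtin energy model ranks duplexes; its absolute energies are not
  substitutes for a folding engine's.
- `threads` is accepted for interface compatibility; the implementation is
  sequential, and the contract is that any future partitioning by sRNA
  must reproduce the same merged, canonically sorted output.
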