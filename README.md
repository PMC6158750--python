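# cleaveseek

Degradome-guided prediction of plant small-RNA targets.

In plants, small RNAs (miRNAs and siRNAs) guide the RNA-induced silencing
complex to near-complementary sites on messenger RNAs, which are then cleaved
between the target bases opposite sRNA positions 10 and 11. Degradome/PARE
sequencing captures the uncapped 5′ ends of the resulting 3′ cleavage
fragments, so each degradome tag whose 5′ end aligns at a transcript position
is direct evidence of a cleavage event there. `cleaveseek` combines both data
types: it finds transcript positions supported by degradome tags, asks which
sRNAs could have guided cleavage there under configurable targeting rules,
and reports the supported sRNA–mRNA interactions with confidence statistics.

It is written for sRNA researchers who have adapter-trimmed sRNA and
degradome libraries (redundant FASTA) and a reference transcriptome (FASTA,
or GFF3 + genome).

## Method

1. **2-bit sequence encoding.** Each base is two bits, a sequence is one
   integer (first base most significant). sRNA and mRNA alphabets use
   *inverse* codes (A=00/11, C=01/10, G=10/01, T/U=11/00), so a sRNA k-mer
   and the mRNA k-mer it pairs with positionwise encode to the same integer:
   exact-complement lookup becomes integer equality, and all 7-mers live in
   [0, 16383].
2. **Degradome alignment.** Tags are encoded per length into ascending-sorted
   lists; every transcript window of each tag length is encoded and binary
   searched (sense strand, exact match). A hit adds the tag's abundance at
   the window start; a tag matching *k* transcriptome positions contributes
   abundance/*k* of *weighted* abundance at each.
3. **Peak categories.** Each signal position is ranked 0–4 relative to its
   transcript profile: unique maximum (0), tied maximum (1), above average
   (2), at/below average (3), singleton read (4). Positions with abundance 1
   are excluded from the average, separating genuine low peaks from
   background degradation.
4. **Candidates and region prefiltering.** A 32-nt window (16 nt each side of
   the cleavage position) is cut around every qualifying peak. Three 7-mer
   regions of the sRNA — R1 (positions 1–7), R2 (8–14), R3 (last seven) —
   and the opposite target regions TR1/TR2/TR3 index a conceptual
   16384×16384 validity matrix per region; candidates grouped by TR2 are
   pruned through the R2 → R1 → R3 cascade. Rows are computed lazily and
   memoized. The filter is conservative by construction: predictions with
   filtering on are identical to predictions with filtering bypassed.
5. **Duplex alignment.** Anchored at the cleavage site (sRNA position 10 ↔
   window position 17), a depth-first search walks to the sRNA 5′ end and
   then the 3′ end, classifying each pair (Watson–Crick, G:U wobble,
   mismatch), branching on single-base bulges up to the gap budget, and
   pruning the moment any rule is broken. Bundled presets: the Allen et al.
   scheme (mismatch 1, G:U 0.5, gap 1, positions 2–13 doubled, cutoff 4, no
   mismatch/wobble at positions 10–11) and the Fahlgren–Carrington variant,
   identical except positions 10–11 are permitted. Every rule is
   configurable via a JSON file. The best alignment is chosen by
   (score, gaps, mismatches + wobbles).
6. **Confidence filters.** MFE ratio = duplex energy / perfect-site energy
   (nearest-neighbor backend bundled; ViennaRNA optional), default cutoff
   0.7. A per-transcript binomial p-value: with q_c the fraction of the
   transcript's signal positions at category ≤ c and n candidate positions
   evaluated, p = 1 − (1 − q_c)^n.

## Worked example

Generate a synthetic dataset with 12 planted interactions plus background
degradation, then run the predictor:

```bash
cleaveseek simulate --n-transcripts 10 --n-sites 12 --background-rate 2 \
    --seed 5 --out synth
cleaveseek predict --transcriptome synth/transcripts.fa \
    --srna synth/srna.fa --degradome synth/degradome.fa --out results
# -> degradome: 12 interactions
```

`results/degradome.results.csv` then contains one row per interaction, e.g.

```
srna_name,srna_sequence,...,transcript_id,cleavage_position,category,...
TAATCAGCCCCTTCCGGGT,TAATCAGCCCCTTCCGGGT,10,83333.3333,T0000,553,1,10,10.0000,71942.4460,0,"5' ACCCGGAAGGGGCTGATTA 3' target
   |||||||||||||||||||
3' UGGGCCUUCCCCGACUAAU 5' sRNA",-37.85,1.0000,0.666667
```

Reading the row: the 19-nt sRNA (raw abundance 10, 83 333 reads per million
of its library) targets transcript T0000 with cleavage at position 553; the
degradome peak there has raw abundance 10 (category 1, a tied maximum on
that transcript), the duplex is perfectly complementary (alignment score 0,
MFE −37.85 kcal/mol, MFE ratio 1.0), and the per-transcript binomial
p-value is 0.67 (this short transcript carries only a handful of signal
positions, so a category-≤1 hit is unremarkable by this statistic — the
planted site is still reported because the p-value filter is optional and
off by default). All 12 planted sites are recovered; the abundance-1
background tags are category 4 and discarded under the default stringent
settings.

The same analysis is available as a library call
(`cleaveseek.predict_targets`) on in-memory objects.

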