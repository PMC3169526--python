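# Methods

## The assay model

A gap-lesion plasmid carries a single-stranded gap whose template strand
contains one site-specific lesion; a co-transfected, lesion-free gapped
plasmid serves as internal control. After incubation in cells, extracted
plasmids transform an *E. coli* reporter strain; the lesion plasmid is
kanamycin-selected, the control chloramphenicol-selected. All sequence
analysis is performed on the newly synthesized (filled-in) strand, read
5'→3', in 0-based half-open coordinates. No strand flipping occurs
anywhere downstream; the 4-nt classification windows are stated on that
strand (`CAAC` opposite the TT lesions, `GCCT` opposite cisPt-GG, the
middle two nucleotides being the Watson–Crick complement of the lesion
dinucleotide).

Quantities:

* repair extent `R = kanR / cmR` per replicate (undefined at `cmR = 0`,
  a hard error);
* TLS extent `E = 100 · R · f`, with `f` the fraction of TLS events among
  scorable sequenced clones (non-TLS products — large deletions and
  insertions from double-strand-break repair of the gap — are repair but
  not TLS);
* relative TLS: each condition replicate paired with the same-id
  reference replicate, `100 · E_cond / E_ref`, then mean ± sample SD
  across replicates; fold-change is the ratio of mean extents;
* mutagenic TLS: percent of TLS events whose category is not accurate.

## Clone classification

Reads are globally aligned to the construct reference with affine gap
penalties (match +1, mismatch −2, gap open −4, gap extend −1) using
Biopython's `PairwiseAligner`. These defaults favour substitution calls
over spurious indels. End gaps are free on both sequences, so vector
sequence beyond the construct or a truncated read produces no edits;
terminal gap columns are excluded from the edit list. Indels are
left-aligned (shifted to the smallest equivalent reference position), so
a deletion in the `AA` of `CAAC` always reports at the first position —
placement in homopolymers is deterministic. The default references are
built so the base preceding/following the window differs from the window
ends, which keeps left-aligned single-nucleotide deletions inside the
window.

Anchor identity is the fraction of matching positions over the two ≥15-nt
anchors flanking the window, computed over anchor positions aligned to a
read base. Positions inside deletions are excluded from the denominator:
a clean 30-nt deletion is a non-TLS *event*, not an unalignable read,
whereas an unrelated insert mismatches everywhere and scores near the
random-DNA identity of 0.25. The scorability threshold is 0.8 — tolerant
of Sanger end noise, far above random.

Category rules, in order:

1. anchor identity < 0.8, window not covered by the read, or an `N`
   inside the window → `UNSCORABLE` (excluded from every denominator);
2. any insertion, any deletion ≥ 2 nt, or a 1-nt deletion outside the
   window → `NON_TLS`;
3. no edits in the window → `ACCURATE`;
4. otherwise, by the window positions hit (substitutions or a single-nt
   deletion): middle (lesion-opposite) only → `TARGETED`; outer flanks
   only → `SEMI_TARGETED`; both → `MIXED`. A deletion counts at the
   (left-aligned) position it occupies. `MIXED` is one exclusive
   category — never double-counted into targeted and semi-targeted.

Design choices where the convention was genuinely open: "large" indels
are not size-defined in the source spectra, which list only single-nt
deletions (Δ) among TLS events — hence rule 2 draws the line at 2 nt and
at the window boundary. The semi-targeted region is exactly the two
window flanks; wider events are not representable in a 4-nt window and
fall into `NON_TLS` only if they involve indels (a substitution two
positions away from the lesion leaves the window accurate and is not
detected as mutagenic — a known limitation shared with the windowed
bookkeeping itself).

Spectrum percentages are computed out of all TLS events, with
`UNSCORABLE` excluded everywhere; with zero TLS events percentages are
reported as undefined (`None`), never as 0.

## Quantification conventions

The TLS fraction is estimated per replicate when every replicate has ≥ 20
scorable clones, otherwise pooled across the condition (flagged in the
output); Sanger depth per replicate is often small, and pooling trades a
little replicate independence for stability. Relative TLS is averaged
over per-replicate ratios (not recomputed from pooled counts), matching
the mean-±-SD-across-experiments presentation convention. All
percentages carry full precision internally; rounding happens only at
presentation.

## Statistics

Spectrum comparisons collapse TLS events to accurate vs mutagenic
(targeted + semi-targeted + mixed, Δ included) and use Pearson's
chi-square on the 2×2 table without continuity correction, computed from
the closed form `n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`; Fisher's exact test
is substituted automatically when any expected count is below 5 (both
methods can be forced). No multiple-testing correction is applied across
lesion panels; raw P values are reported. Bootstrap intervals are
seeded percentile intervals (default B = 2000); replicate summaries use
the sample SD (n−1), undefined and flagged at n = 1.

## Synthetic data generator

The generator emulates the assay's sampling structure per condition and
replicate:

* `kanR ~ Poisson(n_effective · p_repair_lesion)`,
  `cmR ~ Poisson(n_effective · p_repair_control)` — Poisson rather than
  binomial because the number of transfected plasmid copies per cell is
  unknowable; only the ratio is used downstream;
* clone categories ~ multinomial over
  `{ACCURATE, TARGETED, SEMI_TARGETED, MIXED, DEL1, NON_TLS}`;
* sequences by category-specific edits to the reference: a random wrong
  base at a lesion-opposite and/or flank position, a single-nt deletion
  at a lesion-opposite position (`DEL1`), or a 10–50-nt deletion spanning
  the window (`NON_TLS`).

One RNG stream is derived per (seed, condition, replicate, purpose) via
`numpy` SeedSequence keys, so adding a condition never perturbs another's
draws and outputs are byte-identical per seed. Defaults: 1000 effective
plasmids, 3 replicates, 50 sequenced clones per condition, control repair
probability 0.8 (clone depth per condition is an assumption — the
underlying count tables are not machine-readable).

Presets ship for the headline conditions: three lesions in
PCNA-ubiquitination wild-type vs K164R cells (extent ratios 4.4, 3.3 and
2.6; TT CPD ~2% mutagenic in both; TT 6-4 PP 64% vs 35%; cisPt-GG 12% vs
25%; non-TLS fraction 0.05 throughout) and TT CPD / cisPt-GG in Usp1-null
cells (2.3- and 3.8-fold increases). Wild-type repair extents
(0.3–0.5) are plausible assumptions, not reported values; fold-changes
and spectra, which are the reported quantities, do not depend on them.

What the generator does **not** emulate: sequencing chromatogram noise
and base-calling errors, transfection-efficiency variation beyond the
cmR normalization, clone-sampling dependence between replicates, complex
rearrangements other than a single contiguous deletion, and any UV
dose–response mechanism. Passing recovery tests therefore demonstrates
estimator correctness under the assay's idealized sampling model, not
robustness to real-world sequencing artifacts.

Cell-level simulation: per-cell focus counts are zero-inflated Poisson
(positive with probability p, then 1 + Poisson(μ) foci), colony counts
Poisson around the plated expectation.

## Problem sizes and numerical notes

The acceptance script uses 1000 effective plasmids, 10 replicates and
6000 sequenced clones per condition for the spectrum panel (1000 for the
Usp1 panel), which keeps the Monte-Carlo standard error of each recovered
percentage below ~0.6 points and of each fold-change below ~4%; the test
suite uses 150 clones and 4 replicates and checks recovery within 3
Monte-Carlo standard errors. Default references are synthetic 300-nt
sequences (the published plasmid sequence around the lesion is not
printed; only the 4-nt windows are) with unique anchors and no
homopolymer run ≥ 4 nt; users supply real construct sequences via the
JSON config. The Rpa-focus positivity threshold is ≥ 1 focus by default
(presence/absence scoring), configurable; foci fractions warn below 100
cells per group.
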