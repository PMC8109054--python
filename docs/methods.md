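# Methods

## The screen statistic

`poolscreen` analyzes pooled CRISPR knockout screens of the classic
dropout design: a library of sgRNAs is transduced into a cell population,
the population is subjected to selection (here, growth in vivo after
transplantation), and each guide's abundance is compared between the
pre-selection pool (T0) and the end of the assay (T12). The analysis is
deliberately parameter-light and mirrors how such screens are scored in
practice when replicate counts are small and a heavy statistical model is
not warranted:

1. **Normalization.** Raw counts are scaled per sample to reads per
   million after adding a pseudocount:
   `rep[g,s] = (count[g,s] + c) / Σ_g (count[g,s] + c) · 10⁶`, default
   `c = 1`. Each column then sums to exactly 10⁶. The pseudocount keeps
   strongly depleted guides (zero T12 reads; depletions beyond 30-fold do
   occur) finite rather than dropping them, at the cost of compressing
   extreme fold changes slightly toward 1.
2. **Fold change.** `fc[g,r] = rep[g, T12_r] / rep[g, T0]`. A single
   shared T0 — one transduced pool sequenced once, transplanted into
   every recipient — is the default pairing; per-replicate T0 samples are
   paired by replicate id when present.
3. **Median across replicates.** The per-guide median of fold changes
   across replicate animals is the ranking statistic; an even replicate
   count uses the midpoint of the central pair. log2 is applied after the
   median, so the log2 column is always exactly `log2(median_fc)`.
4. **Gene calls.** The threshold is symmetric: a guide is *depleted* at
   median FC ≤ 1/2 and *enriched* at ≥ 2 (|log2| ≥ 1). A gene is a
   **positive regulator** (its loss depletes the cells) when at least 2
   of its guides are depleted and depletion strictly dominates
   enrichment; **negative regulator** symmetrically. Ranking is
   deterministic: direction-relevant guide count (descending), then
   |median of the gene's guide-level log2 medians| (descending), then
   gene name. Nontargeting (NTC) guides are excluded from gene scoring
   and reported separately — their fold change staying inside [0.5, 2] is
   the screen's internal negative control.

No p-values or FDR are computed: with five replicates and a
threshold-count readout, the guide-count criterion *is* the test, and
the simulator (below) is used to verify its false-positive behavior
empirically.

`normalize_to_input(p_out, p_in) = p_out / p_in` covers the companion
competition/homing assays, where a marker-positive percentage after
selection is normalized to the input percentage measured shortly after
transduction.

## Counting

Screen reads share a fixed layout (vector constant region, then the
20-nt spacer), so counting is anchored extraction rather than alignment:
find the first exact occurrence of the anchor within a configurable
search window, take the following 20-mer, and match it against the
library. With a mismatch budget of 1, a read with no exact match is
assigned to a *unique* Hamming-distance-1 neighbor (found by probing all
60 single-substitution variants); two equidistant neighbors make the
read ambiguous — counted as unassigned and tallied separately. `N` never
matches. Conservation holds by construction: assigned + unassigned =
reads processed, per sample. Qualities are parsed but ignored; reverse
complement search is off by default because amplicon primers fix read
orientation.

## Editing quantification

Cas9 cuts bluntly 3 bp 5′ of the PAM, between protospacer positions 17
and 18; `predict_cut_site` maps that bond to forward amplicon
coordinates on either strand. Each amplicon read is globally aligned
(Needleman–Wunsch, unit mismatch and gap costs; the DP rows are
vectorized, ~1 ms per 200-bp read). Tie-breaking is deterministic:
mismatch preferred over opening a gap, deletion over insertion — and an
already-open gap run is extended whenever cost permits, so equal-cost
paths never fragment one indel into several short ones (the contiguity
an affine gap penalty enforces; under pure unit costs fragmentation is
cost-neutral and would bias the editing fraction low by about a point).
Indels are reported left-aligned: a deletion in a homopolymer always
appears at the leftmost equivalent position.

A read is **edited** when its alignment passes the edit-distance filter
(distance ≤ 0.3 × read length; worse alignments are chimeras/garbage and
leave the denominator) and carries ≥ 1 indel overlapping the cut window
— reference bases `[cut−w, cut+w)` for deletions, bonds `[cut−w, cut+w]`
for insertions, default `w = 3`. Overlap is evaluated against the
indel's full cost-equivalence placement range (leftmost to rightmost
shift), so the call does not depend on which canonical placement the
aligner reports inside repetitive sequence. Substitution-only
differences never count as editing, and one read counts once no matter
how many cut-window indels it carries (a read-level "% gene editing").
The ±3 window with unit-cost global alignment is the field-standard
(CRISPResso-like) definition; amplicon-quantification tools differ in
exact window and gap parameters, so fractions are comparable at the
percent level, not the decimal.

## The simulator

`simulate_screen` reproduces the generative structure of an in vivo
screen, with stochasticity only at the sampling stages and selection
acting on expectations (a full birth–death process adds nothing at the
read depths involved):

1. Plasmid pool skew: per-guide abundances ~ lognormal(0, σ), σ = 0.5 —
   pooled cloning never yields a uniform library.
2. Transduction: T0 cell counts ~ Multinomial(N_cells, pool
   proportions), default N_cells = 10⁶.
3. Engraftment bottleneck, per mouse: Multinomial(N_engraft, T0
   proportions), default N_engraft = 2×10⁵ (~400 cells/guide for 486
   guides) — the dominant noise source of transplantation screens.
4. Selection: each guide's cells split into an edited fraction e
   (default 0.9, matching measured editing efficiencies above 90%) whose
   abundance is multiplied by `2^effect` over the assay, and an unedited
   neutral fraction. `effect` is the guide's log2 fitness effect over
   the whole 12-day assay: gene effect (0 unless planted) plus a
   per-guide normal deviation, sd 0.3 by default (sgRNAs against the
   same gene never behave identically). NTC guides have effect exactly
   0. The common baseline expansion cancels in proportions and is
   omitted. The unedited fraction floors achievable depletion at
   (1−e) — with e = 0.9 even an infinitely toxic gene retains 10%
   abundance, about 3.2 log2 units of maximum depletion.
5. Sequencing: counts ~ Dirichlet-Multinomial per sample (shared T0 plus
   one T12 per mouse), depth 5×10⁶ reads. `seq_dispersion` is the mean
   per-guide Dirichlet concentration (the Dirichlet parameter is
   `proportions · n_guides · seq_dispersion`); the default of 1000
   inflates count variance ~11-fold over a pure multinomial at this
   depth, and `seq_dispersion → ∞` recovers the multinomial.

All stages draw from generators spawned off one root `SeedSequence`, so
identical configs give byte-identical outputs. Ground truth (per-guide
effects, per-stage abundances) is emitted for recovery testing, and
`truth_recovery_report` scores classifications against planted effect
signs.

`simulate_amplicon_reads` plants, in a chosen fraction of reads, exactly
one indel (size uniform on 1–10, insertion/deletion by coin flip) whose
span intersects the ±3 cut window, then applies independent per-base
substitution noise (default 1%, substitutions always change the base).

### What the simulator does and does not emulate

It reproduces the features that drive screen statistics: library skew,
finite-cell sampling, the engraftment bottleneck, incomplete editing,
guide-to-guide effect heterogeneity, and overdispersed sequencing. It
does not model clonal dynamics, guide cross-reactivity from multi-locus
homology, PCR jackpotting beyond the Dirichlet overdispersion, in vivo
microenvironment effects, or editing-outcome spectra (each edited cell
is simply "knocked out"). Tests passing on simulated screens therefore
validate the *analysis* under the stated noise model, not the
biological fidelity of any particular real screen.

## Problem sizes and determinism

The test suite runs the full default-size screen (486 guides, 5 mice,
5×10⁶ reads/sample) — simulation plus scoring takes well under a second
— and repeats all-null screens over 20 seeds for the neutrality and
false-positive checks. Editing quantification is exercised at 10,000
reads on a 200-bp amplicon (~14 s). End-to-end FASTQ tests scale read
depth down to a few thousand reads per sample, since emitting and
re-parsing 5×10⁶-read FASTQ files adds nothing statistically. All
randomness flows from explicit seeds; reruns are byte-identical.

## Known limitations

- Hamming-1 rescue probes 60 variants per unmatched read; for libraries
  with near-duplicate spacers the ambiguity tally should be watched (and
  `validate_library(check_near_matches=True)` flags spacer pairs within
  Hamming distance 1 up front).
- The unit-cost aligner is exact but quadratic; it is sized for amplicon
  work (hundreds of bp), not genome-scale alignment.
- With a shared T0, its sequencing noise is common to every replicate's
  fold change and does not shrink with more mice; the median across mice
  only suppresses per-mouse noise.
- The editing fraction is a read-level statistic; allele-level zygosity
  and large structural outcomes are out of scope.
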