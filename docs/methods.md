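# Methods

`fnrscan` infers a minimal regulon for an oxygen-sensing Fnr-family
transcription factor from three genotype-comparison fold-change tables, a
genome with gene annotation, and a map of transcription start sites (TSS).
The design problem it addresses is that a regulator deletion mutant that
cannot grow anaerobically confounds direct regulatory effects with
growth-state effects; the analysis therefore contrasts the regulator mutant
against a respiration-dead but regulation-intact control mutant, and then
corroborates candidate targets by finding a shared DNA box at an
activator-compatible position upstream of their promoters.

## 1. Category classification

Each gene carries three linear ratios: `A` (WT anaerobic / WT aerobic),
`F` (regulator double mutant / WT, both anaerobic) and `N` (nitrate-reductase
mutant / WT, both anaerobic). Ratios are stored linearly; log2 is an
accessor. The rules are a fixed-precedence decision list (first match wins):

| label | rule | reading |
|---|---|---|
| CAT1 | A ≥ t_ind, F < 1, N/F ≥ t_diff | induced; collapsed in the regulator mutant but ≥ t_diff-fold higher in the respiration control — the direct-target signature |
| CAT2 | A ≥ t_ind, F ≤ 1/t_ind, N ≤ 1/t_ind | induction lost in both mutants (growth-state dependent) |
| CAT3 | A ≥ t_ind, F ≥ t_up, N ≥ t_up | even more induced in both mutants (stress of non-respiring cells) |
| CAT4 | A ≤ 1/t_ind, F ≥ t_ind | anaerobic repression lost in the regulator mutant |
| CAT5 | F ≥ t_ind, 1/t_unaff < N < t_unaff | induced only in the regulator mutant |
| UNREGULATED | 1/t_unaff < A < t_unaff | inside the unaffected band |
| UNCLASSIFIED | otherwise, or any ratio missing/non-positive | |

Defaults `t_ind = 3`, `t_unaff = 2`, `t_diff = 3`, `t_up = 2` follow the
3×/2× conventions of the modelled study; all four are config-exposed
because the study prints the 3× and 2× cutoffs but not the CAT2/CAT3/CAT5
auxiliary ones. "At least"-phrased cutoffs are closed (≥), the "less than
twofold" band is open. CAT1 deliberately precedes CAT2: a gene strongly
down in both mutants but ≥ 3-fold higher in the respiration control (the
nitrate-reductase operon pattern) is evidence of direct regulation.
Missing or non-positive ratios are flagged at read time, never imputed, and
classify to UNCLASSIFIED. Manual curation (e.g. a regulator gene deleted in
the mutant itself, whose category is known from independent kinetics) is
supported by a per-gene override table, never by special-cased logic.

`classify_all` also reports two filter counts used as headline numbers:
genes differential at least t_ind-fold in either direction, and — among
those — genes whose expression moved less than t_unaff-fold in both
mutants (the regulator-independent anaerobic response).

## 2. Operons, promoters and box-center geometry

Consecutive same-strand genes merge into an operon when the intergenic gap
is ≤ `max_gap` (default 100 bp; the study infers operons from TSS and
expression continuity without printing a rule, so the cutoff is config)
and no TSS assigned to the downstream-in-transcription gene lies in the
gap. Overlapping same-strand genes merge with a warning. Gene lists are
kept in transcription order, so the lead gene of a minus-strand operon is
the genomically rightmost.

Promoter regions are the ≤ 450 bp immediately upstream of the lead gene's
start codon (or of its TSS when anchored there), written 5′→3′ on the
coding strand and clipped at contig edges. 450 bp is the window the
modelled study used for motif search.

Box centers use the biologist's gapped axis: the TSS is +1, the base just
upstream is −1, and there is no zero. A site occupying positions
`first..last` has center `(first+last)/2`, which is half-integer for
even-width sites fully upstream of the TSS — exactly the convention in
which class II activator sites cluster at −41.5. Sites spanning the TSS
map both bounds through the same gapped axis. Promoter classes are
assigned from center windows inferred from the anchor statements of the
modelled study (−41.5 and neighbours ⇒ class II; −60.5 and −93.5 ⇒
class I; −29.5 ⇒ overlapping the −35 hexamer; −328 ⇒ distal):
class II [−49.5, −35.5]; class I [−110.5, −50.5]; core-overlap
(−35.5, −20.5]; otherwise distal; NO_TSS where no TSS is mapped. Windows
are config.

## 3. ZOOPS EM motif discovery

The motif model is zero-or-one-occurrence-per-sequence: a sequence carries
one site with prior λ (uniform over start positions) or is pure i.i.d.
background. The EM is standard — the E-step computes the posterior over
site starts plus the no-site outcome; the M-step re-estimates the base
probability matrix from posterior-weighted counts with pseudocount
α = 0.25 per base per column (the study is silent on smoothing; α is
config) and λ from expected occupancy. Convergence at Δlog-likelihood
< 1e-6 or 200 iterations. Width defaults to 14 (the production setting of
the modelled analysis, after trying 13–15); other widths are accepted.
Search is on the given strand only; the optional palindrome constraint
symmetrizes expected counts against their reverse complement in the
M-step, which is the constrained maximum-likelihood update and preserves
EM monotonicity. After a motif is accepted its posterior-decoded sites
(posterior > 0.5) are masked to N and discovery repeats, up to `n_motifs`.

**Starting points.** Frequency-ranking of full-width words is vacuous at
W = 14 (essentially every window is unique), so restarts are seeded by a
starting-point screen in the style of MEME: every candidate window is
mapped to a 0.7/0.1 matrix, and because the resulting log likelihood-ratio
of window *j* against candidate *c* decomposes as
`base(j) + log(7)·matches(j, c)`, all candidates are scored with a single
one-hot matrix product. A candidate's score sums, over sequences, the
positive part of its best window LLR; the best `restarts` (default 10)
distinct candidates start full EM runs and the highest-likelihood fit
wins. The screen caps candidates at 6000 (seeded subsample beyond that).
Equivalence with the original MEME analysis is at the level of the
recovered consensus, not internal state.

**Null behaviour.** Maximum-likelihood ZOOPS on signal-free input does not
collapse: with ~440 candidate positions per sequence the EM aligns each
sequence's best random window and reports a ~10-bit motif with λ ≈ 1.
Rejecting such motifs requires occurrence-significance machinery (MEME's
E-values), which is out of scope here; instead a fitted motif is flagged
`low_information` when its relative entropy against the background is
< 6 bits or λ < 0.2 (this catches degenerate, e.g. single-letter, input),
and the test suite checks the relative separation: null-input motifs score
well below planted-signal motifs, and site recovery rises monotonically
with planted information content.

**Consensus rendering.** Per column: an uppercase base at frequency
≥ 0.75; a lowercase `x/y` pair (descending) when the top two bases each
reach 0.25 and jointly 0.75; otherwise N, with runs of ≥ 2 N compressed to
`N_k_` between hyphens. The dyad box of the modelled regulator renders as
`TTGAc/t-N_4_-g/aTCAA`.

## 4. PWM scanning with exact p-values

Window scores are log2 likelihood ratios against an i.i.d. background
(order-0; higher orders are out of scope). P-values are exact under that
model: per-column scores are discretized at ε = 1e-3 bits and their
distributions convolved by dynamic programming, the construction used by
FIMO-class scanners; a window's integer score indexes the null survival
function directly, so scanned p-values carry no additional approximation.
Continuous scores passed to `score_pvalue` are mapped with a
half-bin-per-column tolerance (error ≤ (W/2 + 1)ε bits). The default
report threshold is p ≤ 1e-4 (the conventional FIMO default; the study
prints none), config-exposed. Overlapping hits within one sequence are
resolved greedily, best p first. Scanning is given-strand, with a
both-strand flag for 5′-region scans where orientation is per gene.

**Refinement loop.** Mirroring the study's procedure: (1) discover on a
seed promoter set; (2) rescan a wider promoter set with the motif;
(3) re-discover on the hit-positive subset, seeding EM from the step-1
matrix, to obtain the refined motif; (4) scan the configured target sets
(operons ≥ t_diff-fold up in the respiration control vs the regulator
mutant; operons ≥ t_ind-fold down in the regulator mutant; genes up in the
regulator mutant; genome-wide 5′ regions). An empty hit-positive set
reports the initial motif unrefined, with a warning. In `run_all` the
step-2 set is the lead promoters of all category-assigned operons, a
reading of the study's ambiguous "all the genes analysed in the first
instance" that bounds false-positive dilution of the refined matrix.

## 5. Synthetic data generator

The generator emits genome FASTA, GFF3, TSS table, expression table and a
ground-truth sidecar, reproducible byte-for-byte from one seed. Its
defaults are the modelled study's condition sizes: 1000 genes of which 478
are ≥ 3-fold differential, 102 of those mutant-unaffected, category sizes
26/107/25/57/36, and 12 box-bearing CAT1 operons; box centers are a point
mixture at −41.5 (0.6), −42.5 (0.2), −60.5 (0.1), −93.5 (0.1). The genome
is i.i.d. at GC 0.65 (sphingomonad-like), so background scan statistics
are realistic. Effect sizes are log-uniform per category with at least a
2× margin beyond every rule boundary the category must respect (CAT1
inductions span 9–200-fold, echoing the printed 3-to-200-fold range);
categories whose biology implies similar behaviour in both mutants (CAT2,
CAT3, CAT4) draw N as F times LogU[1/1.5, 1.5] so they cannot leak across
the N/F seed-selection cutoff. Noise is multiplicative log-normal on every
ratio (σ in log2 units, default 0.25) — the standard error model for
expression ratios; the study states none.

Planted motif instances realize the configured per-column frequencies as
exact largest-remainder compositions, with rare ("mismatch") bases spread
across sites so no single instance degenerates; which site receives which
base is seeded-random. This makes the planted frequency matrix — and hence
the rendered consensus — a property of the emitted site set rather than a
sampling expectation, which is what the recovery guarantees are stated
against. Operon layout keeps a divergent promoter pair carrying boxes at
least 800 bp apart so one operon's box cannot fall into the other's scan
window (the near-palindromic box would otherwise cross-hit).

What the generator does *not* emulate: real promoter sequence composition
(σ-factor elements, UP elements, local GC structure), operons spanning
multiple regulatory categories, condition-dependent TSS usage, replicate
or count-level noise, and any correlation between expression magnitude and
sequence. Passing tests therefore demonstrate algorithmic correctness and
recovery under the stated noise model, not performance on real genomes —
on real data the discovery seed set, the p threshold and the class windows
are calibration choices.

## 6. Pipeline, determinism and problem sizes

`run_all` chains simulate/load → classify → operons → promoters →
discover → scan → refine → report under one config and one seed, writing a
manifest (config snapshot, input checksums, per-stage outputs) that
suffices to reproduce the run. All randomness flows from
`numpy.random.default_rng(seed)`; identical seeds give identical outputs
(manifests differ only in timestamp). The default problem sizes — 1000
genes (~1.2 Mb genome), ~620 operons, 450 bp promoters, 20-sequence motif
experiments, 1e6-window p-value calibration — run the full pipeline in a
few seconds and the whole test suite in well under a minute on one core;
they were chosen as the smallest sizes at which every condition count of
the modelled study is representable exactly.

## Known limitations

* Rule cutoffs beyond the printed 3×/2× conventions (CAT2/CAT3/CAT5) are
  this package's defaults and would need calibration against the original
  supplementary tables, which are not redistributable here.
* The operon merge rule (100 bp, TSS-in-gap veto) is a heuristic stand-in
  for the study's expression-continuity curation.
* No motif significance (E-value) statistics; null-input discovery returns
  an overfitted motif that must be judged by its `low_information` flag
  and downstream scan evidence.
* Background model is order-0 i.i.d.; q-values/FDR are not computed.
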