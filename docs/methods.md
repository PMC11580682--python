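# Methods

## Model

`tandemhmm` decodes nucleotide sequence against an HMM with one
nonrepetitive state, one repetitive state per period p = 1…k, and explicit
indel machinery per period. All states and probabilities:

| parameter | meaning | default |
|---|---|---|
| `max_period` (k) | largest detectable repeat period | 100 |
| `match_prob` (m) | Pr[Sₜ = Sₜ₋ₚ] inside a repeat | 0.7 |
| `decay` (λ) | geometric prior over entry periods, γₚ ∝ λᵖ | 0.85 |
| `n_insert` / `n_delete` (i, d) | max consecutive insertions / deletions | 10 / 10 |
| `background` | E₀ over A,C,G,T; set via AT richness (A=T=at/2, C=G=(1−at)/2) | uniform |
| `repeat_entry` | nonrepetitive → repetitive mass (split by γₚ) | 0.01 |
| `repeat_exit` | repetitive → nonrepetitive | 0.05 |
| `indel_open` | repetitive → indel chains (half to I, half to D) | 0.02 |
| `indel_extend` | continue a consecutive-indel chain | 0.2 |

A repetitive state with look-back q emits the letter matching S₍t−q₎ with
probability m; the remaining 1−m is spread over the other three letters in
proportion to the (renormalized) background, which keeps the
relative-emission ratio (1−m)/(1−E₀(S₍t−q₎)) well behaved under composition
bias. The nonrepetitive state emits exactly E₀, so its relative emission is
identically 1 and an all-background path accumulates only transition cost.
Ambiguity letters (N, IUPAC codes) never match and emit at ratio 1, which
prevents N-runs from being annotated. Positions closer to the sequence
start than a state's look-back also emit at ratio 1; the −p start
adjustment of reported regions compensates for the units this hides.
Deletion-offset chains whose look-back would drop below 1 (deletions deeper
than the period) also emit at ratio 1.

The published source for this model family does not print its transition
defaults; the values above are this package's own choices, of plausible
magnitude, and every quantitative claim in the test suite is made at these
stated values. All decoding arithmetic is in natural-log space; equivalence
tests use 1e−9 tolerances.

## Decoding

Each window is filled with the relative-emission Viterbi recurrence. The
implementation keeps one value track per repetitive period plus the
background track and treats every offset (J) chain as a unit: a circular
buffer holds the chain's in-flight excursions, each advanced by one
addition per column — the identical floating-point operation the naive
per-J-state dynamic program performs, in the same order, so the two are
bit-for-bit equal (property-tested). The win is the absence of per-offset
transition processing, max() scans and stored backpointer columns;
traceback through a chain is reconstructed arithmetically from its entry
column. Silent deletion states are resolved within a column in chain
order; no silent cycles exist by construction.

Ties are broken deterministically everywhere: lower period first, then
non-indel over indel states, then lower state id, applied from the final
position backwards.

Windows are auto-sized as `clamp(1e8 cells / state count, 10 kb, 1 Mb)`
with overlap `max(4·(k + max(i,d)), 100)`. Regions from adjacent windows
are merged: equal periods (and, with a gap of at most 15 unannotated
letters, periods sharing a common factor — harmonics) are fused with score
s₁ + s₂ − overlap·min(density₁, density₂); overlapping regions of
incompatible periods are truncated at the overlap midpoint on the
lower-scoring side, its score scaled by the retained fraction. Harmonic
fusion matters because a period-p repeat under substitution noise is
statistically almost indistinguishable at look-back p and at its multiples:
the score difference between the two tracks is a zero-drift random walk
that can exceed any reasonable period-switch cost over a few hundred
letters, so Viterbi paths occasionally fragment a single repeat into
harmonically related pieces. Fusing them (at the common period) and letting
the splitting scan re-examine the merged region is self-correcting: a
genuine pattern change inside the fused region is re-found as a split.
Profile-index phase cannot be stitched exactly across window boundaries,
so merged regions rebuild their index track as a pure cycle.

Region scores use the per-step sum (entry transition included), which
telescopes to a difference of two matrix entries; the identity is exact up
to floating-point cancellation, which grows with window length (matrix
values drift by ≈ −0.01 per column on background), hence the telescoping
test decodes a megabase in 50 kb windows where agreement is ~1e−10.

## Repeat splitting

Profile indices cycle 1…p, with `*` on inserted letters (no phase advance)
and a skip of j indices after a depth-j deletion. Two adjacent windows are
summarized as p×4 row-normalized frequency profiles with a pseudocount of
0.01 per cell, and compared by the symmetrized Kullback–Leibler divergence
summed over profile indices. Three numerical choices are this package's
own, made where the method description leaves them open, and matter in
practice:

* **Base-2 logarithms.** The divergence is measured in bits — the
  conventional unit — and the default threshold 3.5 is calibrated on that
  scale. In bits, a single fully-swapped profile row at 10% substitution
  scores ≈ 4.1 (> 3.5), so period-2 unit pairs that differ in only one
  position remain detectable; in nats the same signal is ≈ 2.9 and would
  be invisible.
* **Adaptive window size.** Windows must hold ≥ 15 letters and ≥ 5 units,
  and additionally grow to a quarter of the region, capped at 150 letters.
  The sampling noise of the divergence between two identical-content
  windows is ≈ p²·3/w ln 2 bits, so the bare minima would drown the
  threshold in noise for mutated or large-period repeats.
* **Two-stage peak refinement.** Peaks are detected with the large window
  (strict local maxima, leftmost on plateaus, greedy acceptance with one
  window length minimum separation) and then re-localized with the
  minimum window within ±2·wmin, restoring ~unit-level localization.

Subrepeat consensus units take the majority letter per profile index (ties
alphabetically first); units are named by their lexicographically least
rotation (Booth's algorithm); adjacent subrepeats with rotation-equivalent
units are merged to a fixed point.

## Calibration and tuning

Null calibration annotates seeded i.i.d. background (default 10 Mb — a
desk-scale default; scale up for production parameters) and fits a shifted
exponential to region scores by maximum likelihood (μ = minimum, σ = mean
excess), with ω the fraction of letters annotated. P(s) =
min(1, ω·exp((μ−s)/σ)). ω is a per-letter prefactor (~10⁻³ on random
sequence), so P-values of null regions concentrate below ω; calibration
quality is therefore checked on the survival scale: the number of fresh
null regions beyond the fitted (1−q) quantile must match q·(region count),
and the log-survival of null scores must be linear (R² ≥ 0.98 on 10 Mb of
60% AT-rich input at k = 100).

Tuning shuffles the input locally (window = the decoding window by
default; 20 kb is conventional for genome-scale evaluation), preserving
regional composition while destroying true tandem repeats, and estimates
each candidate's FDR as shuffled coverage / original coverage. The winner
maximizes coverage subject to FDR ≤ 0.10 (ties: higher match probability,
then lower decay). Indel states are disabled during tuning for speed and
re-enabled in the final configuration; the built-in grids hold 18, 40 and
252 configurations over AT richness, match probability and decay
(documented in `tune.builtin_grids`).

Relative emissions discount chance matches correctly only when the
background reflects the local composition: a pure-AC sequence scored
against a uniform background looks repetitive letter-for-letter
(chance-match rate 0.5 vs the expected 0.25). The AT-richness
parameterization can express AT/GC skew but not purine/pyrimidine skew;
`--tune` is the intended remedy for unusual compositions.

## Synthetic data

The two-subrepeat benchmark concatenates two perfect 500-letter tandem
tracts whose units (same period, sampled by rejection) share ≤ 50%
positional identity under every relative rotation, then applies uniform
substitution noise (each mutated letter becomes one of the three other
letters uniformly). Units are additionally required to be primitive (no
smaller rotational period); a non-primitive unit would change the tract's
true period and make the junction ill-defined. Accuracy is the fraction of
sequences with exactly one reported split within 10 nt of the junction;
the suite runs 200 trials per period/rate condition (a scaled-down version
of the 5000-trial experiment; pass `trials=5000` for the full version).
The planted-genome generator embeds non-overlapping tandem tracts
(periods ≤ 10, geometric lengths of mean 300, 5% substitutions) into
i.i.d. background to a target coverage; it emulates repeat density and
decay, not indel evolution, higher-order repeat structure or real
isochore-scale composition variation — so passing tests bound behavior on
this class of inputs, not on real genomes.

Problem sizes used by the test suite and the acceptance script (1 Mb
telescoping and tuning runs, 10 Mb calibration, 200-trial benchmark) are
the package's chosen desk-scale experiment sizes; the underlying routines
take arbitrary sizes.

## Known limitations

* DNA/RNA only; no protein alphabet.
* Only runs of ≤ i insertions / ≤ d deletions are modeled; complex indel
  patterns are approximated by consecutive ones.
* Viterbi point decoding only (no posterior per-letter probabilities).
* The merged-score formula across windows and the truncation rule for
  incompatible overlapping periods are approximations chosen to avoid a
  second decoding pass.
* P-value parameters are composition- and parameter-specific; they are not
  re-estimated automatically during tuning.
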