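# tandemhmm

Annotation of tandem repeats in DNA and RNA with a context-sensitive hidden
Markov model.

Tandem repeats — adjacent copies of a short unit, from microsatellites like
`AACAACAAC…` to megabase satellite arrays — are both biologically important
and a major source of false positives in homology search. Once a repeat has
accumulated substitutions and indels, simple pattern matching fails;
`tandemhmm` locates such decayed repeats, assigns each region an
interpretable log-odds score and P-value, names its repeat unit, and marks
internal changes of repetitive pattern.

## The model

A single *nonrepetitive* state emits letters from a background composition
E₀. For every period p = 1…k there is a *repetitive* state whose emission
is context-sensitive: at position t it re-emits the letter S₍t−p₎ with
probability m (default 0.7) and spreads the remaining mass over the other
letters in proportion to E₀. Entry into a period-p repeat is weighted by a
geometric prior γₚ = λᵖ / Σ₍q≤k₎ λ^q (λ = 0.85), so small periods are a
priori favored. Insertions and deletions are modeled explicitly: up to
i consecutive insert states (background emission), up to d consecutive
silent delete states (i = d = 10 by default), each followed by a dedicated
chain of p *offset* states whose look-back is shifted to p+j (after j
insertions) or p−j (after j deletions) before control returns to the
period-p state — so an indel costs one event, not p spurious mismatches.

Decoding uses a Viterbi recurrence over **relative** emissions,

  P′₍t,v₎ = maxᵤ P′₍t−1,u₎ · T₍u,v₎ · E₍t,v₎ / E₍t,0₎ ,

so emissions on the all-background path contribute exactly zero and a
region's score is a log-odds against background. Maximal non-background
runs of the Viterbi path become repeat regions (the reported start is
shifted left by p, since a look-back model cannot place the first unit on
the path), scored by

  score = Σₜ [ log T₍v₍t−1₎,vₜ₎ + log (E₍t,v₎/E₍t,0₎) ] ,

which telescopes to a difference of two matrix entries. Long inputs are
decoded in overlapping windows (auto-sized from the state count) and
re-merged; the offset-state chains are updated in aggregate per chain,
bit-identically to the naive per-state dynamic program.

Post-processing: each region's letters get cyclic *profile indices* 1…p
(`*` for inserted letters); two adjacent sliding windows are summarized as
p×4 letter-frequency profiles and compared by the symmetrized
Kullback–Leibler divergence (bits). Peaks above 3.5 mark *repeat splits*;
the resulting *subrepeats* are named by the lexicographically least
rotation of their consensus unit, and neighbors whose units are rotations
of one another are merged back (the signature of an undetected indel).
Scores are converted to P-values with a shifted-exponential null fitted on
random sequence: P(s) = ω·exp((μ−s)/σ), with ω the fraction of null
letters annotated. A `--tune` mode grid-searches parameters, estimating
each candidate's false discovery rate as coverage of a locally shuffled
input divided by coverage of the input, and picks the highest-coverage
candidate under a 10% FDR.

## Worked example

```bash
tandemhmm demo.fa --period 10 --insertions 0 --deletions 0
```

on a 560 bp sequence containing `(AAAC)×50 (GGTT)×50` embedded in random
background prints

```
seq_id  start  end  record_type  period  score     p_value  pattern  indel_events  parent
demo    81     480  region       4       372.9142           AAAC     0
demo    81     280  subrepeat    4                          AAAC              region_0
demo    281    480  subrepeat    4                          GGTT              region_0
```

one period-4 region (TSV coordinates are 1-based inclusive; BED output is
0-based half-open) covering the full planted array, scoring ≈ 373 nats
against background, split at position 280/281 — the true junction between
the `AAAC` and `GGTT` tracts — into two subrepeats named by their
canonical units. With `--pval --ploc MU --pscale SIGMA --pfreq OMEGA`
(e.g. from `tandemhmm.calibrate.calibrate()`) the score column is
accompanied by a P-value.

The library mirrors the CLI:

```python
from tandemhmm import ModelParams, annotate_sequence
regions = annotate_sequence(seq, ModelParams(max_period=10))
```

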