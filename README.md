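# rhythmflow

Symbolic-recurrence quantification and information-flow analysis for pairs
of people improvising rhythm together.

When two players create music by trading percussive strikes, the structure
of their collaboration is written into the two sound-amplitude time series:
how repetitive each rhythm is, whether the players prefer a few patterns
over others, how much information the two streams share, and in which
direction influence flows.  `rhythmflow` implements that analysis chain for
paired amplitude envelopes (one per player, one sample every 150 ms, T = 800
samples for a two-minute trial), together with the permutation machinery
needed to say whether an observed pair shows more coordination than two
people who never played together, and a regression stage linking the
information metrics to the players' musical expertise.

## The statistics

Each scalar series $\{x_t\}_{t=1}^{T}$ is symbolized by ordinal patterns of
length $m$ (default $m=3$): window $(x_t,\dots,x_{t+m-1})$ maps to the
permutation that sorts it ascending, giving $\bar T = T-m+1$ symbols on an
alphabet of $m!$ patterns.  Ties are broken by temporal order.  The
symbolic-recurrence plot marks every time pair $(t,s)$ sharing a symbol
$\pi$; counting recurrences gives

$$SRR(\pi) = \frac{c_\pi(c_\pi-1)}{\bar T(\bar T-1)}, \qquad
  SRR = \sum_\pi SRR(\pi), \qquad
  P(\pi) = \frac{SRR(\pi)}{SRR},$$

and the recurrence entropy $H = -\sum_\pi P(\pi)\log_2 P(\pi)$ (bits).  An
i.i.d. series has $SRR \to 1/m!$ and $H \to \log_2 m!$; rhythmic playing
shows higher SRR and lower H.  For a dyad, the same construction on symbol
*pairs* (an $(m!)^2$ alphabet) yields the pair-level SRR and joint entropy
$H(x,y)$, and on lagged triples the conditional entropies, from which

$$I_{xy} = H(x)+H(y)-H(x,y), \qquad
  TE_{y\to x} = H(x_{t+1}\mid x_t) - H(x_{t+1}\mid x_t, y_t).$$

Significance is assessed with a re-pairing null: the 2N individual
recordings of a session are re-matched into N artificial pairs uniformly at
random, the metric recomputed, and the observed mean compared against
20,000 resampled means (two-sided for SRR/entropy, one-sided for MI/TE).
Mutual information and received transfer entropy are then modelled with
gamma/log-link GLMs on expertise predictors (within-pair sum/difference of
collaboration experience and years of practice for MI; focal/partner scores
for TE), each term tested with a Type-II likelihood-ratio $\chi^2_1$.

A fully seeded synthetic dyad generator provides ground truth: each
simulated player repeats an evolving motif on a 150 ms pulse grid, and
player B copies player A's previous slot with probability `coupling_eps`,
so directional influence is known by construction and every stage of the
pipeline can be calibrated end to end.

## Worked example

```python
import rhythmflow as rf

cfg = rf.DyadSimConfig(coupling_eps=0.6, seed=42)   # A drives B
dyad = rf.generate_dyad(cfg)

prof = rf.srr_profile(rf.symbolize(dyad.series_a, m=3))
print(f"player A: SRR = {prof.srr:.3f}, H = {prof.entropy:.3f} bits")

dm = rf.dyad_metrics(dyad.series_a, dyad.series_b)
print(f"I_xy = {dm.mi:.3f}  TE A->B = {dm.te_a_to_b:.3f}  "
      f"TE B->A = {dm.te_b_to_a:.3f}")
```

prints

```
player A: SRR = 0.267, H = 1.436 bits
I_xy = 0.337  TE A->B = 0.731  TE B->A = -0.005
```

Player A's rhythm recurs far above the i.i.d. rate (0.267 vs 1/6) with a
concentrated pattern distribution (1.44 vs 2.58 bits).  The transfer
entropy is large only in the direction that was actually coupled; the
slightly negative reverse value is the small-sample behaviour of the
uncorrected plug-in estimator on a direction carrying no signal.  The
re-pairing test on a 12-pair cohort of such dyads gives an observed mean MI
of 0.224 bits against a null 97.5th percentile of 0.077 (p ≈ 0.001).

The same pipeline runs from the shell:

```bash
rhythmflow simulate --pairs 30 --seed 7 --out data/
rhythmflow all --simulate --pairs 30 --seed 7 --out results/
```

writing per-pair metric tables, null summaries, session comparisons, model
summaries, figures, and a manifest that pins the configuration and seed.
Recorded data are analysed the same way from a
`pair*/session*/player*.{wav,csv}` directory layout.

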