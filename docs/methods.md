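# Methods

This note documents the models, estimators and design choices behind
`rhythmflow`, in the spirit of a statistical package's methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The unit of analysis is a non-negative amplitude envelope per player,
sampled every `dt_s = 0.15` s — the order of an auditory reaction time — so
a 120 s trial yields T = 800 samples.  When starting from PCM WAV audio,
the absolute waveform is aggregated over non-overlapping `dt_s` bins.  The
default aggregate is the per-bin **maximum** of |amplitude|: percussive
onsets are impulsive, and point-sampling or averaging can miss or dilute a
strike that the maximum always retains.  An RMS aggregate is available
(`aggregation: rms`) for signals where energy rather than onset amplitude
is the quantity of interest.  A partial trailing bin is discarded, so
T = floor(duration / dt_s) regardless of sub-bin tail length.

Trimming an initial backing-track segment is supported
(`skip_head_s`) but **off by default**: the primary configuration keeps the
full two minutes, which is what T = 800 corresponds to; enabling a 15 s
exclusion yields 700 samples and is a configuration choice, not a code
path difference.

## Symbolization

Ordinal patterns of length `m = 3` (alphabet 3! = 6) are the default;
`m = 2` and `dt_s = 0.10` are the robustness alternatives exposed in the
run configuration.  Exact ties within a window — common in percussive data
during silent runs — are broken by temporal order (earlier offset ranks
lower), implemented as a stable argsort; this is the standard ordinal-
pattern convention.  An optional seeded dither (`dither > 0`) breaks ties
stochastically instead; it changes nothing for continuous-valued input and
is intended for heavily quantized recordings.

## Recurrence statistics

All quantities are computed from symbol counts.  With $c_\pi$ occurrences
of pattern $\pi$ among $\bar T$ symbols, the number of ordered off-diagonal
recurrence pairs is exactly $c_\pi(c_\pi - 1)$, so the count closed form
equals the explicit double loop over the recurrence plot; the test suite
verifies this identity against an independent brute-force implementation to
1e-10.  The recurrence matrix itself is materialized only for plotting and
tests.

The recurrence *probability* distribution $P(\pi) = SRR(\pi)/SRR$ weights
each pattern by its collision count, not its frequency.  A recurrence-free
series has an empty recurrence distribution: its entropy is reported as NaN
with an explicit `entropy_defined = False` flag rather than 0, since a
zero entropy would falsely assert perfect pattern preference.

## Mutual information and transfer entropy

Dyadic quantities are entropies of tuple-symbol recurrence distributions:
pairs $(S_x(t), S_y(t))$ on $(m!)^2$ cells for MI, triples
$(S_x(t{+}1), S_x(t), S_y(t))$ on $(m!)^3$ cells for TE, with conditional
entropies via the chain rule $H(A|B) = H(A,B) - H(B)$.  The TE lag is one
sample (one `dt_s` step) and configurable.

Two estimation modes are provided, and the choice matters in small
samples:

- **literal** (default): each entropy comes from the recurrence profile of
  its own tuple series — the direct reading of the defining equations.
  The combination of separately estimated entropies is not constrained to
  be non-negative; slightly negative MI/TE values occur on directions
  carrying no signal.
- **joint-marginal**: all entropies derive from the largest tuple
  distribution by marginalization.  MI and TE are then genuine (conditional)
  mutual informations of one distribution, hence non-negative, and this is
  the mode in which estimator-consistency statements are cleanest.

No small-sample bias correction is applied in either mode.  The plug-in
bias is real and is characterized empirically in the calibration tests: for
*uniformly* symbol-rich series (i.i.d. input, all 6 patterns equally
active) the bias at T = 800 is an order of magnitude larger than the
0.02-bit calibration bound and only falls below it around T = 10,000.
Rhythmic material is different: its symbol distribution is concentrated on
few patterns, the effective alphabet is small, and the bias at T = 800
stays in the 0.01-bit range.  This is why calibration statements at study
scale are made on the synthetic dyad generator (rhythmic, concentrated)
and the i.i.d. limits are verified at T = 10,000.  The re-pairing null
inherits whatever bias the estimator has, so permutation inferences are
bias-matched by construction.

## Synthetic dyad generator

The generator produces what the metrics actually consume — envelopes — from
a fully controllable event process:

- **Pulse grid.** One potential strike per sample (`tempo_period = 1`,
  i.e. every 150 ms; sixteenth notes at 100 bpm).  Coarser grids are
  supported, but a grid whose strikes land only on a sub-lattice makes the
  symbol law phase-dependent, and two independent players sharing that
  clock then show spurious mutual information; the per-sample grid keeps
  slot statistics homogeneous in time.
- **Motifs.** Each player repeats an 8-slot cell; slots hold velocities in
  [0.3, 1] with probability `hit_prob = 0.3`, else rest.  Each visited slot
  mutates with probability `motif_noise = 0.1` — persistently, so the motif
  evolves rather than resetting, supplying the innovations that make
  influence measurable (two fully deterministic players transfer no
  information).
- **Phase slips.** With probability `phase_slip = 0.1` per pulse a player
  repeats or skips a slot.  This emulates human tempo drift and is
  essential for calibration: without it two independent same-length motifs
  stay phase-locked on the shared grid forever, which is statistical
  dependence without any coupling.  Slips turn the relative phase into a
  mixing random walk, so independent dyads decorrelate within a trial.
- **Envelope.** A strike resets the envelope to its velocity; between
  strikes it decays by `decay_per_sample = 0.8` (time constant ≈ 0.67 s, a
  ringing-percussion scale); additive noise (`noise_sd = 0.01`) is folded
  in last and the result clipped non-negative.  Sparse strikes with slow
  decay concentrate the ordinal-symbol distribution the way real rhythmic
  playing does, which keeps the plug-in bias at T = 800 well under the
  coupling signal.
- **Coupling.** With probability `coupling_eps` per pulse, player B's
  emitted slot copies player A's realized slot one pulse earlier.  The copy
  is transient (B's internal motif is untouched) and consumes only B's
  random stream, so `coupling_eps = 0` means B is bit-identical whatever
  A's stream does.  Ground-truth direction is therefore unambiguous, and
  the generator's event log (emitted slots per pulse) is stored in
  `SyntheticDyad.truth` for direct verification.

Synthetic cohorts attach expertise: Likert collaboration scores sampled
from the proportions observed in a 60-participant university survey
(12/11/17/13/7 for scores 0–4), years of practice loosely increasing with
the score, and a logistic link
`coupling_eps = sigmoid(-2.0 + 0.35 * (score_a + score_b))` spanning
roughly 0.12–0.69.  The follower role and coupling strength persist across
the two sessions, so within-pair consistency is built into the ground
truth.

What the generator does **not** emulate: real marimba timbre and pitch
choice, tempo as a continuous (non-grid) quantity, nonstationary arousal
or learning within a trial, and any audio mixing between players.  Passing
calibration on this generator therefore demonstrates correctness of the
estimators and inference machinery under controlled coupling — not that
any particular human dataset will show a given effect size.

## Re-pairing permutation null

For one session with 2N individuals, each resample draws a uniform random
perfect matching into N pairs (shuffle, take consecutive elements), and
the mean metric over artificial pairs is stored; transfer entropy
contributes both directions per pair (2N values).  The observed pairing is
not excluded from the matchings — excluding it would bias the null for
small N — and self-pairing is impossible by construction.  Note assignment
is ignored in re-pairing.  The p-value uses the add-one estimator
(never exactly zero); the percentile rule (outside 2.5–97.5 for two-sided,
above 95 for one-sided) is reported as a separate boolean, since it is the
rule the original analysis frames its decisions in.  Default 20,000
resamples; tests run at 999.

Pair-level SRR and entropy are computed on the **joint** pair-symbol
recurrence plot.  A univariate per-pair statistic would be invariant under
re-pairing, making the null degenerate; the joint reading is the one under
which the re-pairing comparison is informative.

## Session comparisons and expertise models

Between-session changes use a paired t-test (df = N−1) and within-pair
consistency a Pearson correlation (df = N−2); a zero-variance difference
is flagged degenerate rather than reported as t = 0 silently.

The GLMs use a gamma error distribution with log link.  Both trait
families (collaboration score, years) enter one model by default, each
with its within-family interaction; `families="separate"` fits them
separately, and both conventions are reported by the pipeline when asked.
Term tests are Type-II likelihood-ratio chi-squares on 1 df: deviance
differences between marginality-respecting nested fits, scaled by the full
model's Pearson dispersion.  This reproduces the R `car::Anova(type = 2,
test = "LR")` convention, verified against a frozen R reference fit in the
test suite.  Gamma support requires positive responses; if non-positive
MI/TE rows occur (possible under the literal estimator), the response
column is shifted so its minimum is 1e-4 bits, with a warning — the shift
is reported in the fit object.  The TE model treats the two players of a
pair as independent rows, replicating the original design; the ignored
within-pair dependence is a known limitation.

## Problem sizes and numerical conventions

Calibration runs use the study scale (T = 800, N = 30 pairs) with reduced
resample counts where full-scale repetition would be wasteful: permutation
calibration uses 999 resamples per null (400 null cohorts for the type-I
rate, 60 coupled cohorts for power), estimator calibration 50 seeds, and
regression recovery 100 replicates of N = 500 gamma cohorts.  i.i.d.
limits are averaged over 100 seeds at T = 10,000.  Entropies are in bits
throughout; 0·log 0 = 0; equality oracles are enforced at 1e-10; seeds are
derived from a single master seed via `numpy` seed sequences and all
reported quantities are deterministic given it.

## Known limitations

- The plug-in entropies are uncorrected; absolute MI/TE values at T = 800
  carry positive bias for symbol-rich signals and should be interpreted
  against the re-pairing null, not as calibrated information rates.
- The literal estimation mode can return small negative MI/TE; the
  joint-marginal mode exists for analyses that need non-negativity, and
  the two agree asymptotically.
- The triple-tuple alphabet (216 cells for m = 3) is large relative to
  T̄ ≈ 800 samples; no occupancy correction is applied.
- Expertise models assume independent rows; pair-level random effects are
  out of scope.
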