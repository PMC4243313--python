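# Methods

## The model

A scored hypnogram is treated as a realization of a continuous-time Markov
chain (CTMC) over a small vigilance state space, observed only at epoch
boundaries.  The chain is described by a generator matrix `Q` whose
off-diagonal entries `q_rs` are instantaneous transition intensities
(units 1/s); each diagonal entry is minus its row's off-diagonal sum.  Two
derived quantities carry the scientific interpretation:

* **sojourn time** `S_r = 1 / Σ_{s≠r} q_rs` — the expected residence time in
  state `r` between two jumps;
* **normalized transition rate (NTR)** — the hazard ratio of a treatment
  group's intensity over the reference group's for one specific transition.

Group effects are log-linear per transition (proportional intensities):
`q_rs(g) = q0_rs · exp(β_rs,g)` with `β ≡ 0` for the reference group, so the
NTR is exactly `exp(β_rs,g)`.  Each non-reference group contributes one free
`β` per allowed transition; no random effects are fitted — subjects are
independent chains sharing their group's parameters.

Because hypnograms record the state only at epoch starts (panel data), the
likelihood of a consecutive epoch pair `(s_t, s_{t+Δ})` is the matrix
exponential entry `P(Δ)[s_t, s_{t+Δ}] = expm(QΔ)[s_t, s_{t+Δ}]`, not an
event-time density.  The log-likelihood sums over all pairs of all subjects;
pairs never span a segment boundary because segments are separate sequences.

### Phases and state spaces

Early recovery sleep is strongly non-stationary: wakefulness decays over the
first half hour and REM is rare.  The pipeline therefore fits two separate
time-homogeneous models instead of one joint model:

* **onset phase** (default 0–2000 s): two states, WAKE vs SLEEP (NREM and
  REM merged), 2 transitions → 4 descriptive parameters per group (2 rates +
  2 sojourns);
* **steady phase** (default 2001 s–end): three states WAKE/NREM/REM, 6
  transitions → 9 descriptive parameters per group.

A single model with a phase factor is not possible here because the two
phases use different state spaces.

### Estimation and inference

Free parameters `(log q0, β)` are unconstrained; the likelihood is maximised
by BFGS with an analytic gradient built from Fréchet derivatives of the
matrix exponential.  The start value is the pooled crude-rate generator
`q_rs = N_rs / T_r` (pair counts over holding time, with unobserved
transitions floored at 1e-6 s⁻¹) and `β = 0`; the fitted log-likelihood is
verified to improve on this start.  Convergence is declared when the
gradient max-norm falls below `max(1e-5, 1e-8 × number of observed pairs)`:
the gradient scales with the pair count, so for large panels the residual
gradient after double-precision rounding cannot reach an absolute 1e-5.
Non-convergence produces a flagged result and a warning, never an exception.

The covariance of the estimates is the inverse observed information,
obtained by centred finite differences of the analytic gradient at the
optimum (eigenvalue-clipped to keep it positive semi-definite).  All
intervals are 95% Wald intervals computed on the log scale — for a sojourn
time via the delta method (`S · exp(±1.96 · SE_log S)`), for an NTR directly
from `β ± 1.96 · SE_β` — so intervals are always positive and contain the
point estimate.  Significance follows the CI rules only, with no p-values:
an NTR differs from the reference when its CI excludes 1, and two estimates
differ when their closed CIs are disjoint (endpoint contact counts as
overlap, the conservative reading).  Whether published analyses of this kind
used Wald or profile intervals is generally unstated; Wald is the standard
choice for this model class and is what is implemented.

Transition probabilities are floored at 1e-300 before the log; floor hits
are counted in the fit diagnostics.

## Standard sleep metrics

Computed per subject from the fine six-stage vocabulary (AW, PW, SWS1,
SWS2, IS, REM), with WAKE = AW+PW, NREM = SWS1+SWS2+IS, SLEEP = NREM+REM:

* total time, episode count, mean episode duration per class (an episode is
  a maximal run, minimum one 4-s epoch);
* **sleep fragmentation** — awakenings disconnecting sleep.  Counted at the
  fine level: every AW/PW episode inside a wake bout flanked by sleep on
  both sides counts separately (AW→PW→AW counts 3); a bout-level variant is
  available behind `level="bout"`;
* **REM latency** — first REM epoch start minus first sleep epoch start.
  "Start of sleep" is the first epoch of *any* non-wake stage, not
  specifically SWS-1; this choice is deliberate and would only differ when a
  recording reaches IS/SWS-2/REM before any SWS-1;
* **SWS-1 / SWS-2 latency** — first occurrence relative to lights-on
  (the `start_time` origin);
* **first REM item** — length of the maximal REM+IS run anchored at the
  first REM epoch and extending forward only; IS before the first REM epoch
  is excluded;
* **REM-attempt filter** (optional, off by default): REM runs separated by
  gaps shorter than 16 s merge into one item; items spanning less than 16 s
  have their REM epochs relabelled to the dominant stage of the item's
  internal gaps (isolated runs borrow the preceding epoch's stage; ties
  prefer the preceding stage).  The filter never increases REM time.

Undefined latencies (stage absent) propagate as missing values and are
dropped pairwise from group statistics with a logged count.

Group comparison is a two-way fixed-effects ANOVA with factors treatment
(VEH/SSRI) and rebound (HC/RD) plus their interaction, using Type-II sums of
squares because group sizes of 6–7 are mildly unbalanced, followed by Tukey
HSD over the four cells.  With balanced cells the Type-II F statistics
coincide with the classical sums-of-squares decomposition, which the test
suite checks against a from-scratch oracle; the interaction test's type-I
error is calibrated by null simulation.

## Spectral analysis

Each 4-s epoch at 128 Hz (512 samples) yields a Hanning-windowed
magnitude-squared spectrum at 0.25-Hz resolution, truncated to
1.25–60.00 Hz (236 points; the 0–1 Hz range is dropped).  Power is
*absolute power per bin with coherent-gain correction*: a unit-amplitude
sinusoid on a bin centre contributes its mean-square power 0.5 regardless of
the window.  No normalization to power density per Hz or percent-of-total is
applied by default, since the upstream convention is ambiguous on this
point; relative output can be derived from the returned tables.

Quarter-Hz points are summed into 1-Hz bins labelled by their **upper**
limit (bin 2 = 1.25–2.00 Hz, …, bin 60 = 59.25–60.00 Hz), and bins into
bands: delta = bins 2–4, theta = 5–9, alpha = 10–13, beta = 14–30, gamma =
31–60.  Delta "1–4 Hz" deliberately maps to bins 2–4: the 0.5–1 Hz range is
omitted from analysis even though scoring criteria describe slow waves from
0.5 Hz.  Both aggregations are exact partitions, so total power is conserved
(up to summation rounding).

Stage averages are arithmetic means over a stage's epochs with the artifact
mask false, optionally restricted to an analysis window; averaging is
permutation-invariant and stages left with zero usable epochs are marked
absent.  Artifact *detection* is out of scope — masks are inputs.

## Synthetic data

The simulator draws exact event-time CTMC paths (exponential holding times,
competing-rate destinations) and discretizes by reading the state at each
epoch start — the same observation model the likelihood assumes.  A
majority-vote labelling variant was considered and rejected as the default
because it breaks that correspondence; state-at-start is also what an
idealized instantaneous scorer would report.  Chains start in the first
state of the vocabulary (WAKE); at the simulated durations (≥2000 s against
sojourns ≤174 s) the initialization transient is negligible.

Study designs mirror a four-group rodent rebound-sleep experiment: groups
HC-VEH (reference), HC-SSRI, RD-VEH, RD-SSRI with 6, 7, 7, 7 subjects,
2-h recordings, 4-s epochs.  The reference generators use published
control-group sojourn times (onset: WAKE 174.131 s, SLEEP 35.239 s; steady:
WAKE 17.199 s, NREM 46.758 s, REM 32.844 s) with **equal destination
splits**, because the source tables report exit scales and relative rates
but not the reference group's destination split; this choice is recorded in
the design metadata.  Group effects are per-transition intensity multipliers
taken from the published NTR tables, so the simulation truth for every NTR
is the published point estimate.  Consequently simulated *NTRs* match the
published ones by construction while simulated group *sojourns* need not —
they depend on the unknown split.

Per-subject random streams derive from
`SeedSequence([design seed, group index, subject index])`, so datasets are
reproducible and subjects independent.  A six-stage fine-vocabulary design
(plausible hand-chosen rates, steady-phase multipliers mapped onto their
fine analogues) feeds the metrics and spectra steps; its collapse to three
states is not exactly Markov — which is realistic, as scored hypnograms are
not either.

Synthetic EEG assigns each stage a small set of sinusoids plus white noise,
following the visual scoring signatures (REM: 7 Hz theta; SWS-2: 2 Hz
high-amplitude; SWS-1: 2.5 Hz plus 12 Hz spindles; IS: 12.5 Hz spindles with
5.4 Hz theta; AW/PW: low-amplitude 20 Hz).  Phases are redrawn per episode.
What passing tests show is therefore that the pipeline attributes power to
the correct stages and bands and recovers known generators — not that it
handles amplifier drift, scorer disagreement, artifacts beyond the supplied
mask, or circadian non-stationarity within a phase, none of which the
generator emulates.

## Problem sizes used in the acceptance script

Recovery runs use 50 sequences × 20,000 s for single-group sojourn checks
and 25 + 25 sequences × 20,000 s for two-group NTR checks (about 10× the
information content of the emulated 2-h study, chosen so that sampling noise
sits well inside the quantities' confidence intervals); the ANOVA
calibration uses 1000 null replicates of a balanced 2×2×7 design, and the
spectral check one 2-h six-stage recording.  The replicate-coverage test in
the suite uses 50 replicates of 7 + 7 subjects × 7200 s, the emulated study
scale per replicate.

## Known limitations

* Time-homogeneity within a phase is assumed, not tested; phase boundaries
  are fixed by configuration, not estimated.
* No hidden/semi-Markov structure: scoring noise and dwell-time
  distributions other than exponential are not modelled.
* Wald intervals can undercover for transitions with very few events; an
  unidentified β yields an infinite upper CI rather than an error.
* The ANOVA assumes independent subjects and homoscedastic cells; metrics
  with many undefined values lose subjects pairwise.
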