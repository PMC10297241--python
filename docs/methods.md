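# Methods

`neoprd` implements a pipeline for detecting intraventricular haemorrhage
(IVH, grade II–IV) in extremely preterm infants from early-life cerebral
(rcSO₂) and peripheral (SpO₂) oxygen-saturation monitoring. The central
object is the *prolonged relative desaturation* (PRD): a transient dip of
roughly 2–15 minutes, defined by signal decomposition rather than by any
absolute saturation threshold. This note records the model, the concrete
numerical choices, and what the synthetic experiments do and do not show.

## Signal model and preprocessing

Raw channels are nonuniformly time-stamped saturation series. Cerebral
oximeters record at ~1/5–1/6 Hz with external storage ("external"
dialect) or ~1/34–1/35 Hz on internal memory ("internal"); pulse
oximeters at 1 or 0.5 Hz. Preprocessing:

1. **Amplitude artifact rules.** rcSO₂ samples pinned at the 15 % device
   floor (probe detached) are deleted together with a 30 s collar on
   each side. SpO₂ samples < 20 %, and sample pairs changing faster than
   4 %/s (both members), are deleted with the same collar. The collar is
   interpreted as two-sided — 30 s before *and* after each flagged
   sample; a one-sided or total-width reading would halve the guard.
2. **Uniformisation.** Surviving samples are cubic-spline interpolated
   onto a 10 Hz grid, low-pass filtered with a zero-phase FIR
   (Blackman-windowed sinc, passband edge at half the target Nyquist,
   stopband at the target Nyquist 1/12 Hz, > 70 dB attenuation; zero
   phase via symmetric taps, reflection padding and delay compensation)
   and decimated to the 1/6 Hz analysis grid.
3. **Gap invalidation.** Grid samples whose value was interpolated
   across a raw gap longer than 2× the nominal sampling period are
   marked invalid: short gaps are timestamp jitter, long ones are real
   dropouts. Invalid samples are excluded from all downstream statistics.

Input already on the exact target grid bypasses the spline/FIR chain
unchanged; this fast path is what makes preprocessing idempotent (a
second pass changes nothing), which no finite interpolation + FIR chain
achieves on its own.

## PRD extraction (DCT + SSA)

Each contiguous valid segment of at least 2 h is decomposed:

1. Subtract the segment mean and take an orthonormal type-II DCT. A
   time-localised transient becomes an amplitude-modulated oscillation
   in the transform domain whose oscillation rate encodes the event's
   *position*; distinct events therefore map to distinct narrowband
   structures.
2. Singular spectrum analysis of the DCT coefficient sequence: Hankel
   embedding with window L, eigendecomposition of the L×L Gram matrix
   (built in O(LN) by per-lag cumulative sums), and diagonal averaging
   of each rank-one term back to a series. Using σv = Xᵀu directly makes
   the sum of all elementary series reconstruct the input to machine
   precision regardless of conditioning.
3. **Grouping.** A component joins the PRD component when (a) its
   variance share exceeds 0.5 % and (b) the spectral centroid of its
   time-domain reconstruction lies in 0.12–5 mHz. A unipolar dip of
   duration D has its centroid near 1/(4D), so this band covers 2–15 min
   events with headroom at the long end; drift components sit well below
   it and the broadband noise floor is excluded by the variance floor.
4. A 1-h running median of the summed component — which tracks
   hour-scale wander but is insensitive to ≤ 15-min dips — is returned
   to the residual. The residual is defined as original − PRD component,
   so the additive identity holds exactly on every sample.

Choices that differ from the obvious first guesses, and why:

* **Window L = 360 samples.** In the *time* domain an SSA window brackets
  the time-scales separated; in the *DCT* domain it governs the
  resolution of event positions. L = 120 (20 min) could not separate
  events closer than ~1.5 h in a 24 h record and silently merged them;
  L = 360 resolves the event spacings the generator produces at ~1/h.
* **Variance floor 0.5 %.** Events of 8 % depth in a 24 h record carry
  ~0.5–1 % of total variance; a 1 % floor dropped them, while noise
  components sit near 0.15–0.35 %.
* The grouping rule as a whole is this package's concrete instantiation
  of a "data-driven" transient selection; it is a documented stand-in,
  not a replication of any published grouping criterion.

**Event segmentation.** Events are maximal excursions of the PRD
component below −3 %, extended on each side to the effective zero
crossing (first sample above 8 % of the run nadir — a literal zero is
hostage to numerical ripple) and capped at 300 s per side (a real dip's
flank from the detection core to zero is < 4 min even for a 15-min
event; longer stretches are adjacent wander). The −3 % threshold sits
well below the 11–14 % grand-average event depths yet above recovery
noise. The per-event baseline is the residual at onset; the nadir is the
minimum of the *original* signal inside the event; slopes are the
straight lines baseline→nadir (negative, %/min) and nadir→baseline at
offset (positive). Only negative excursions are events: these are
desaturations.

Measured on the generator's default conditions (50 seeded 24-h
artifact-free recordings per experiment, events 2–15 min and ≥ 8 % deep):
nadir-depth MAE ≈ 1.2–1.4 % saturation and duration MAE ≈ 78–85 s, with
0–6 missed events per 230 and a median of zero detections on event-free
recordings.

## Feature sets

**Per-epoch features (66).** A dyadic bank of five zero-phase FIR
filters with bandwidths a/2ᵇ (a = fs/2, b = 0…4), read as *nested
low-pass* filters with cutoffs fs/2 … fs/32 — the literal reading of the
bandwidth formula; an octave band-pass tiling is available behind
`FilterBankSpec(mode="octave-bandpass")`. Per 4-h epoch (50 % overlap →
2 h step) and band: envelope mean/SD/5th/95th percentiles (envelope =
magnitude of the analytic signal of the mean-removed series plus the
mean, so a constant c has envelope |c|); skewness and kurtosis of the
band signal itself (Pearson, non-excess kurtosis — conventions the
feature list leaves open); instantaneous-frequency mean/SD/skewness/
kurtosis/5th/95th percentiles (IF = central finite difference of the
unwrapped analytic phase, one-sided at the ends); and the Higuchi
fractal dimension (kmax = 8, a common default with stable fits on the
2400-sample epochs). 13 × 5 bands + postnatal age at the epoch midpoint
= 66. Epochs with < 75 % valid samples become all-missing rows — the
tree learners handle missing values natively, and no validity rule is
prescribed elsewhere.

**Per-recording PRD features (14).** Event rate per valid hour; total
power of the PRD component; envelope mean/SD and Hjorth activity/
mobility/complexity of the whole PRD component over valid samples (not
of event-concatenated segments — the alternative reading); inter-event
interval mean/SD measured nadir-to-nadir; time below 63 % rcSO₂ (85 %
SpO₂) on the *original* signal, which doubles as the stand-alone
threshold comparator; and event-averaged nadir amplitude, down/up slopes
and duration. Zero-event recordings keep rate = 0 and power ≈ 0 but
leave morphology missing; zero-filling would fabricate zero-depth
events.

## Models and evaluation

Signal models are XGBoost classifiers with the fixed study settings
(depth 3, 50 trees, learning rate 0.1); the clinical model is a 500-tree
random forest on one row per infant (sex, hypotension, inotropes,
chorioamnionitis, gestational age, birth weight, 5-min Apgar, head
circumference). Cross-validation is leave-one-infant-out: all rows of
the held-out infant leave the training table, and the held-out rows'
probabilities are averaged to one per-infant probability (the
aggregation is not prescribed; the mean is this package's choice, with
the median behind a switch). SpO₂ models add per-fold
`scale_pos_weight` = n_neg/n_pos. Signal and clinical probabilities
combine by geometric mean (late-stage fusion). Fold seeds derive
deterministically from the global seed and the infant id.

Evaluation: Mann–Whitney AUC (ties at half weight); 95 % percentile
bootstrap CI with 1000 resamples drawn per infant (count unspecified
upstream; single-class resamples are discarded, redrawn and counted);
sensitivity/specificity/accuracy at probability ≥ 0.4 (inclusive);
Matthews correlation with a zero denominator reported as 0; an AUC is
*significant* iff both the estimate and the lower CI bound exceed 0.5.
Per-feature AUCs are computed on raw feature values without orientation
correction, so values below 0.5 flag inverted direction. The
grand-average event curve aligns every event's original-signal excursion
(relative to its baseline) at the nadir on a ±20 min grid and averages
within outcome groups. Fisher's exact test (two-sided, hypergeometric)
compares outcome prevalence between sampling dialects.

## Synthetic cohort generator

The generator is the study's stand-in for non-shareable patient data.
Per infant: baseline ~N(70, 4) % rcSO₂ (93 % SpO₂), slow drift (two
sinusoids, periods 2–4 h and 5–12 h, 3 % amplitude), 1/f measurement
noise with 1 % SD (oximeters average internally, so sample-to-sample
noise is small; the 1/f exponent is a generic choice for slow
physiological signals), recording lengths drawn 48–72 h, dialects 70 %
external / 30 % internal, dropout gaps at 0.2/h (exponential, mean
5 min) and floor-clipped episodes at 0.1/h (mean 1 min, forcing rcSO₂ to
exactly 15 % so the collar rule is exercised). PRDs arrive at 1/h —
a free parameter; no per-hour rate is reported anywhere — with
lognormal durations (median 7.5 min, clipped to 2–15 min) and an
asymmetric gamma-like waveform (beta-bump, fall twice as steep as the
recovery, matching the asymmetric recovery seen in averaged event
curves; a Gaussian shape is available). Cohorts default to 46 infants
with 12 positive labels, SpO₂ present for ~32/46, and clinical
covariates drawn from the published group summaries. The injury group's
rcSO₂ event depths average 14 % vs 11 % (the reported ~11–14 % relative
changes); SpO₂ depths carry *no* group effect, mirroring the null SpO₂
findings.

What passing the synthetic experiments shows: the decomposition
recovers events of the assumed morphology at realistic noise, the
features transmit a depth difference of 3 % saturation into a
leave-one-infant-out AUC well above chance, and the same pipeline stays
at chance when no effect exists. What it does not show: performance on
real NIRS data, whose artifacts, autoregulation dynamics, event
waveforms and label noise the generator does not attempt to model; the
published cohort's AUC values are not reproducible without the patient
data and are not targets of any test here.

## Problem sizes and runtime

The canonical experiments (`neoprd.studies`) use 50 recordings of 24 h
for the recovery study, the full 46-infant cohort at 48–72 h for the
discrimination study, and 20 cohorts of 40 infants at 24 h for the null
study — together a few CPU-minutes. Repeated experiments use 24-h
records because every structural property (grid, segmentation, epoch
logic, event statistics) is already exercised at that length; the
single discrimination cohort keeps the full-length distribution.

## Known limitations

* Events shorter than ~1 min are outside the detection design, as are
  positive excursions.
* Valid segments shorter than 2 h contribute nothing to the PRD
  component; their events are unrecoverable by construction.
* Hjorth mobility/complexity are reported in per-sample units (the
  first-difference definition carries no explicit dt).
* The percentile bootstrap is mildly anticonservative at n = 46; the
  CI-coverage test asserts ≥ 85 % coverage, not 95 %.
* At very small cohorts (n ≲ 10) leave-one-out prevalence shifts can
  invert per-infant probability rankings — a known LOO artifact, visible
  in the generator's own small-cohort smoke tests.
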