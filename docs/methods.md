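# Methods

This note documents the models, parameter choices and numerical decisions
behind `oddballerp`, and what the synthetic-data generator does and does
not emulate.

## The paradigm and its generator

The oddball block is a sequence of 800 syllables (80% standard /ki/, 10%
deviant /ka/, 10% deviant /ti/) at a fixed 1400 ms onset-to-onset
interval, each deviant preceded by at least three consecutive standards.
Counts are exact (`round(n·p)`), not expected values. Sequences are drawn
uniformly over all valid sequences: a valid sequence factorizes uniquely
into a weak composition of the spare standards over the gaps around the
deviants (sampled by stars-and-bars) and a uniform ordering of the deviant
identities. The constraint is exposed as a parameter and defaults to
three preceding standards; an adaptive shortening of the interval for
fast responders is deliberately not modelled (no deterministic rule can
be stated for it), which keeps the 19-minute block ceiling exact.

## Syllable synthesis

Syllables are source-filter synthesized: a band-limited pulse train with
a falling pitch glide (104 → 88 Hz) plus 5% aspiration noise is passed
through two-pole resonators at (F1, F2) — /a/ = (730, 1284) Hz,
/i/ = (278, 2139) Hz, bandwidths 80/120 Hz. The stop consonant is a 10 ms
band-limited noise burst (center 1400 Hz for velar /k/, 4000 Hz for
alveolar /t/) followed by a 40 ms F2 onset transition from the
consonant's locus (the vowel's F2 for /k/, 1800 Hz for /t/). The pitch
glide smears harmonics so the long-term spectral peaks sit on the formant
resonances rather than on individual harmonics; output is 300 ms and
RMS-normalized. This is a caricature of natural logatome recordings:
adequate for driving the vocoder and the paradigm, not a phonetics model.

## Noise vocoder

Band boundaries are equally spaced in basilar-membrane millimetres using
the Greenwood map with the standard human constants A = 165.4 Hz,
a = 0.06 /mm, k = 0.88 and a 35 mm membrane (the map's 20.7 kHz basal
limit is consistent with the 20 kHz upper analysis edge). With four bands
over 0.2–20 kHz the interior edges fall at ≈ 809, 2493 and 7145 Hz.
"12th order, zero-phase" is implemented as a designed 12th-order
Butterworth band-pass applied forward–backward (second-order sections for
stability at the 20 kHz edge); the envelope filter is likewise a designed
4th-order low-pass at 250 Hz applied forward–backward. Both orders are
exposed in `VocoderSpec`, so the alternative reading (half the order,
squared by the two passes) is one configuration change. The modulated
noise carrier is re-filtered by the band filter before summation —
without this the four modulated wide-band carriers overlap completely and
the band structure is destroyed; the option is toggleable
(`refilter_carrier`).

A note on the stop-band contract: a Butterworth band filter is −6 dB *at*
its design edges, so energy integrated from exactly the edges outward is
≈ −17 dB relative to in-band for any faithful implementation. The
out-of-band leakage metric therefore measures energy beyond a 1/3-octave
guard band that covers the transition skirt; there the re-filtered
vocoder sits below −47 dB while an un-refiltered variant fails by tens of
dB, which is the distinction the check is meant to make.

## Forward model and EEG simulation

Electrodes are an idealized 30-channel extended 10/20 montage on the unit
sphere, exactly mirror-symmetric about the mid-sagittal plane (derived
from standard positions by symmetrizing left/right pairs). Sources are
current dipoles at a uniform depth (eccentricity 0.69) in a homogeneous
conducting sphere (radius 9 cm, σ = 0.33 S/m); surface potentials use the
Legendre-series solution, 120 terms, which at this eccentricity converges
far beyond float precision requirements. Six-source "auditory" patches
sit at mirrored temporal locations; their orientations are tangential,
pointing superiorly — the spherical stand-in for the cortex normal of the
supratemporal plane — which is what gives the simulated N1 its
frontocentral maximum with polarity inversion at temporal sites. A single
midline parietal radial source generates the P3b. Scattered radial
sources fill out the space for the inverse problem. Gain is expressed in
µV per nA·m.

Per trial the generator adds component kernels (unit-peak raised
half-cycles with Gaussian tapering; widths 40/70/250 ms for N1/P2/P3b —
matched to the analysis windows, not claimed as physiology) at the true
latencies, scaled so the noiseless scalp ROI mean peaks at the true
amplitude. Background noise is 1/f-power noise, spatially correlated
across channels via a smooth angular-distance covariance (length scale
0.8 rad) — volume-conducted background is strongly correlated between
neighbouring electrodes, and this matters for the behaviour of the 4-SD
rejection criterion. Blinks are 300 ms biphasic transients at Poisson
rate 0.1/s with a frontal-dominant topography and a dedicated EOG
channel; the implant artifact is a stimulus-locked pedestal (5 ms cosine
ramps, spanning the 300 ms stimulus) spatially concentrated around the
implant-side temporal electrode, default 40 µV.

Default effect structure (the study conditions): via the CI ear the N1 is
30% smaller and 20 ms later, the P2 30% smaller and 10 ms later, the P3b
50 ms later; the difficult deviant's hit probability is ~0.70 for
proficient and ~0.20 for non-proficient users (vs ~0.91 for the easy
deviant), and its P3b amplitude is yoked to the subject's discriminability
(9 µV × hit probability), the coupling the paradigm is designed to
expose. Auditory-patch gains are contralateral-dominant, most strongly
(1.6 : 1, right over left) for left-ear stimulation; right-ear CI
stimulation is near-symmetric. Response times are shifted lognormals
(CI: 380 ms shift, µ = ln 220, σ = 0.35; NH: 320 ms, ln 180, 0.35),
truncated to 210–1190 ms so scored hit rates estimate the true hit
probability; false alarms occur on 2% of standards.

What the generator does **not** emulate: realistic cortical geometry or
conductivity layering, CI electrode-array fields, non-stationary alpha or
muscle activity, heavy-tailed artifacts other than blinks, or response
errors correlated over trials. Passing tests therefore demonstrate that
the *pipeline machinery* is correct and recovers injected effects at
realistic SNR — not that real patient data would yield these numbers.

## Preprocessing decisions

- Kaiser FIR filters are designed with `kaiserord` for 60 dB at the
  specified transition width, forced to odd length (type I, integer group
  delay, compensated exactly); the DC gain is pinned (unit for low-pass,
  null for high-pass) by a ~1e-7 per-tap correction.
- The amplitude criterion computes each channel's SD over the samples of
  all segments pooled and rejects a segment when any channel's peak
  absolute value exceeds 4 SD. With ~40 Hz bandwidth and 30 correlated
  channels this rejects blink-laden segments reliably and a modest
  fraction of clean segments (the extreme-value tail), matching how the
  criterion behaves on real data.
- ICA is FastICA (a fixed-point non-Gaussianity maximizer), components
  ordered by explained variance, count set to the numeric rank,
  deterministic by seed. Component selection is automated: the
  CI-artifact score is |corr(activation, stimulus-on boxcar)| × the
  fraction of squared topography weight on the three electrodes nearest
  the implant-side temporal site (threshold 0.5); the ocular score is
  |corr(activation, EOG)| (threshold 0.7; the frontopolar mean
  substitutes when no EOG channel exists). Thresholds are declared
  configuration, replacing the manual inspection of the original
  workflow.
- Spherical-spline interpolation uses the Perrin kernel with order m = 4,
  50 Legendre terms and regularization 1e-5 (the operator matches MNE's
  implementation to ~1e-5, which serves as an independent oracle in the
  tests).
- Epoch sample windows are half-open with the onset sample included; all
  times are in ms relative to stimulus onset.

## Source analysis decisions

Source-stage epochs span −200…500 ms so the −200…0 ms noise-covariance
baseline exists alongside the −100…400 ms sensor window; sensor-level
P3b measurement uses an extended −100…950 ms epoch because the 300–900 ms
peak window cannot fit in a 400 ms epoch. The covariance is shrunk 10%
toward its diagonal (30-channel covariances from short baselines are
otherwise ill-conditioned). SNR defaults to 3 (λ² = 1/9), the
conventional choice for evoked averages. The source covariance is a
scaled identity — no depth weighting, defensible because the synthetic
geometry has uniform source depth; the scale fixes
trace(G R Gᵀ) = trace(λ²C). The gain matrix is re-referenced to the
common average inside the inverse, and `apply_dspm` enforces (not
assumes) average-referenced input. ROI time courses are means of
absolute dSPM values; exact ties in every peak scan resolve to the
earlier latency, and boundary peaks are flagged.

## Statistics decisions

The mixed ANOVA uses the classical weighted-means split-plot partition
with subject-nested error strata (verified against pingouin for the
one-between/one-within case, including unbalanced groups, and against the
closed-form one-way F). Greenhouse–Geisser ε is computed per
within-effect from the pooled within-group covariance of orthonormal
effect contrasts, ε = tr(S)²/(d·tr(S²)) clipped to [1/(k−1), 1], and
applied when the effect has more than one numerator df and either
ε < 0.75 or a Mauchly test rejects at 0.05 (a singular contrast
covariance counts as rejection). Generalized η² uses all error strata in
the denominator; partial η² is also emitted. Between-group follow-ups
use Welch's t (Satterthwaite df), paired follow-ups the classical paired
t with Cohen's d = mean(diff)/SD(diff); every follow-up family is
Holm-adjusted and family sizes are logged in the report. When a subject
has no measurable average in some cell (e.g. zero hits for the difficult
deviant at small trial counts), that subject drops out of the affected
repeated-measures analysis.

## Problem sizes

Full study conditions are 800 trials per ear at 1000 Hz acquisition. The
cohort-level simulations and the validation studies run scaled-down
versions as the package's own defaults: 200-trial studies (exact
80/10/10 composition) simulated directly at the 500 Hz analysis rate for
the statistics battery, 60-trial subjects for the 100-subject N1-latency
recovery study, 40-trial runs for the 100-run lateralization study, 120
trials for the artifact-cleaning demonstration, 4000 replicates for the
t-test calibrations and 2500 for the mixed-ANOVA calibration. The
acceptance script reports each quantity with the problem size used.

## Known limitations

- The spherical forward model cannot express realistic depth/orientation
  variation; absolute dSPM magnitudes are not comparable to
  individual-anatomy pipelines (the statistic's contracts — scale
  invariance, localization, symmetry — are what is tested).
- The two-stage chain's stage-2 often removes nothing when segment
  rejection has already discarded the blink-laden segments; this is an
  honest consequence of running rejection before the second ICA.
- The P3b peak, a windowed maximum, is upward-biased at low trial
  counts; at scaled-down study sizes this bias can mask the
  P3b-amplitude/hit-rate coupling that larger (full-size) runs recover.
- The vocoded-syllable condition for controls reuses the measurement-path
  generator with condition-specific truth; it does not re-synthesize
  audio per trial.
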