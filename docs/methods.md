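# Methods

## Video tracking

Frames are single-channel grey images of a square arena whose 1.8-m
side spans the frame; this is the only calibration source, so
`px_per_m = downscaled_side_px / 1.8`.  Each frame is reduced to ¼ of
its original size by area interpolation (block mean) before detection;
because coordinates are reported in metres through the downscaled
calibration, the reduction factor cancels from every metric output.

Detection is a fixed grey-level threshold (default 128; the hen is
darker than the pale floor) followed by connected-component labelling;
the largest component inside the `[min_area, max_area]` pixel gates is
the hen, and absence of any admissible component is a valid outcome
recorded as an undetected frame.  A local-mean adaptive threshold is
available as a config option.  The ellipse fit is moments-based: with
second central moments of the mask, the axes are `4·√λ₁` and `4·√λ₂`
(the exact values for an ideal filled ellipse) and the orientation is
`½·atan2(2μ₁₁, μ₂₀ − μ₀₂)`, reported in degrees counterclockwise from
the image x-axis (y up) and folded to [0, 180).  A `1/12`-pixel
integration term keeps very thin masks from degenerating.  Masks under
5 px are treated as no detection.  The blob centre of mass and the
fitted-ellipse centre are both emitted; for clean masks they coincide,
and the movement metrics default to the centroid.

Undetected frames keep their slot in the record stream with empty
geometry, so every downstream window can measure its own detection
fraction and the record count always equals the frame count.

## Movement metrics

Windows are tumbling 10-s spans; the per-window path length is the sum
of displacements between successive detected centroids within the
window.  "5-cm movement within a 10-s period" is read as cumulative
within-window path length (not net displacement) — the stricter
reading, and the quantity the tracker naturally accumulates.  A
stationary window (path < 5 cm) contributes zero to the distance
moved, so sub-centimetre detection jitter cannot inflate distance;
this suppression can be disabled.  A trailing partial window is kept
with its stationarity threshold pro-rated to its width (configurable
to drop instead).  Windows with under 50 % detected frames are
stationary-indeterminate: they count toward neither the stationary
time nor the move ratio's denominator.

The move ratio is moving over non-moving time from those windows; a
track with no stationary windows yields `inf` (a defined sentinel
excluded from ratio statistics) and a fully stationary track yields 0.
Because the raw ratio exceeds 1 whenever hens move most of the time,
a logit transformation of it is undefined; the module therefore also
emits the moving fraction moving/(moving + non-moving), and the
statistics layer applies logit to the fraction while the raw ratio
takes a log₁₀ path.  Both are reported so the choice is explicit.

Shape is minor/major per detected frame; its SD uses the population
(ddof = 0) convention so a two-state alternation of 1.0/0.5 gives
exactly (0.75, 0.25).  The detection filter excludes hens strictly
below 75 % detection; 75.0 % exactly is included.

## Acoustics

The short-time transform uses a periodic 1792-sample Hann window, an
8192-sample DFT and a 200-sample hop at 48 kHz, i.e. a 5.859-Hz
frequency grid and 88.84 % overlap; power is magnitude squared with no
further scaling (the quantile measures are scale-free).

Syllable segmentation is automated: a frame is voiced when its summed
power inside the analysis band (default 200–2000 Hz, covering the hen
fundamental) exceeds a threshold, by default half the maximum in-band
frame energy of the recording.  The relative default means faint,
indistinct sounds fall below threshold and are left unmeasured, while
an absolute threshold can be passed for level-calibrated recordings.
Onset/offset resolution is one hop (≈ 4.2 ms).  Each syllable's
fundamental band is the contiguous frequency extent above 10 % of the
peak of its mean spectrum, grown outward from the peak.  Externally
drawn selection boxes (a selection-table CSV) can be re-measured with
the same math, so manual measurements remain reproducible.

Energy-quantile frequencies use the discrete cumulative energy over
bins with a left-bin convention: the q % frequency is the first bin
where the cumulative reaches q % of the total.  This guarantees the
ordering chain f₅ ≤ f₂₅ ≤ f₅₀ ≤ f₇₅ ≤ f₉₅ and exact equivariance
under whole-bin spectral shifts.  Quantiles are computed on linear
power by default; a dB-weighted variant (floored 60 dB below peak) is
a flag, since display software conventions differ.  Call grouping
splits strictly above 25 ms — a gap of exactly 25 ms stays within the
call.  Per-hen aggregation reports both the total syllable count and
the mean syllables per call.

## RFID ranging

Pairing is a two-state machine per hen over time-sorted directional
reads: `out` from the inside state opens an episode, `in` from the
outside state closes it.  A same-direction repeat keeps the first read
and discards the later one (first-read-wins maximises episode
coverage); a leading `in` and a trailing unmatched `out` are also
discarded.  Every event ends up in an episode or the discard log, so
`events = 2·episodes + discarded` always.  Episodes spanning midnight
are split at the day boundary for per-day totals (configurable); with
pop-holes closed after sunset this is rare by construction.

Classification is strict: *indoor* means zero days with an episode,
*outdoor* means an episode on every available day (45 days by
default), everything else is intermediate.  Selection ranks outdoor
candidates by mean daily outside time (over available days)
descending, takes indoor candidates from the zero-ranging pool, and
breaks all ties by tag id so a rerun selects identically.  Cells short
of the 20-hen quota yield a partial selection with a warning.

## Statistics

Latencies are censored at the 300-s test maximum and enter the models
as 300 s (no survival likelihood is used).  Tonic-immobility induction
allows up to 5 attempts, with the duration taken from the attempt that
held at least 10 s.  Zero latencies under log₁₀ are handled by a
configurable additive offset (documented default 0; pass `offset=1`
to map 0 → 0).

Mixed models are fitted by REML through statsmodels' MixedLM with the
pen as grouping factor, an optional bird-level variance component for
repeated measures, and the transformed response.  Fixed-effect terms
get Wald F-tests with the residual denominator df — an approximation;
finite-sample df corrections (Kenward–Roger, Satterthwaite) are not
available in the engine, and the reported df should be read
accordingly.  Nonsignificant interaction terms (α = 0.05) are removed
and the model refitted.  Least-squares means are population-averaged:
the design row for a level is the average design over the observed
data with that factor set to the level, giving model-adjusted cell
means ± SE on the transformed scale.  Post-hoc pairwise t-tests on
LS-means apply a Bonferroni multiplier only when there are more than
3 comparisons.  Boundary (zero) variance estimates and non-convergence
are surfaced as a `singular` flag, never hidden.

## Synthetic data

The generators define the validation conditions.  Trajectories live in
a 1.8-m arena with a 15 %-of-side margin so the rendered blob never
clips at the frame edge; the `scheduled` profile moves in straight
billiard lines at piecewise-constant speed so path length is
analytically `speed × duration` per segment (wall reflections between
sample points can shave at most one frame-step per bounce, well under
the 3 % oracle tolerance).  The rendered hen is a filled dark ellipse
(default 0.30 × 0.18 m, grey 60 on background 200) — a dark hen on
pale wood; dropout removes the blob from a Bernoulli-chosen subset of
frames, emulating the real tracker's failure on paler hens.  The
default source resolution of 360 px (90 px after the ¼ reduction)
keeps tests fast while still exercising the downscale step; tests
needing finer shape resolution render at 720–960 px.

Audio syllables are Tukey-windowed pure tones at their fundamental —
no vocal-tract realism, harmonics or noise — so every spectral measure
has a known answer.  RFID schedules place episodes inside pop-hole
hours and inject false reads as same-direction duplicates 2 s after a
genuine read.

Study tables use a cohort of rearing treatment (3 levels) × ranging
class (2 levels) with pens nested in rearing (3 pens each, 9 total).
Latencies are log₁₀-normal per cell (baseline 10^1.9 ≈ 80 s, SD 0.45
log units, pen SD 0.08) censored at 300 s; per-minute counts are
Poisson with a log-linear minute slope for outdoor hens (the
ranging × time interaction) and a hen-level log-normal frailty
(SD 0.3) — the simplest count model consistent with rising outdoor
activity, not a claim about any real flock.  Feather totals come from
a latent √total that can be negatively coupled to the log step
latency, discretised into six 1–4 parts.  All generators are
deterministic given their seed.

What passing tests show — and what they do not: the synthetic scenes
are single uniform blobs on clean backgrounds, tones are pure, and
count models are Poisson; real videos have shadows, occlusion and
pale-plumage contrast failure, real calls have harmonics and noise,
and real counts may be overdispersed.  The tests validate the
measurement math and the inferential plumbing, not field performance.

## Problem sizes

The validation suite uses 5-min videos at 240–360 px for record-count
and oracle checks, 1–3-s audio clips, 45-day RFID schedules for a
handful of hens, and 500-replicate null simulations with 60-hen
cohorts for the type-I check (10 hens per cell keeps each mixed-model
fit around 50 ms).  These sizes were chosen as the smallest at which
each property is cleanly observable.
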