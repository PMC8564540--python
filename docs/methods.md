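# Methods

## Soundscape reconstruction protocol

A soundscape for one site-year is built on an initially empty (all-zero)
canvas, 300 s by default at 44.1 kHz. For each counted individual of
each species, in the order species appear in the count table:

1. a clip is drawn uniformly from that species' standardized clip set;
2. a start time is drawn uniformly on `[0, canvas_s − clip_s]`;
3. a playback gain is drawn from the gain distribution —
   `Uniform(0.05, 1.0)` by default (strictly positive, so every
   individual is audible; the upper bound matches the −6 dBFS headroom
   of the sources), or a half-normal `|N(0, 0.4)|` clipped to
   `[0.01, 1]` to emulate a higher share of distant singers;
4. `gain × clip` is added into the canvas.

Mixing is a plain floating-point sum: no clipping, limiting or
normalization is ever applied before index computation, so the canvas is
an exact linear superposition of its insertions (tested to 1e−12 by
rebuilding canvases from their insertion provenance). Rescaling happens
only on WAV export, and only if the peak exceeds full scale. Because the
randomized choices change the indices from build to build, each
site-year is built `n_iter = 5` times and each index is averaged across
iterations.

Randomness uses one master seed with per-(site, year, iteration)
substreams derived by SHA-256 hashing of the labels, so whole runs are
bit-reproducible and any single soundscape can be rebuilt in isolation.

## Clip standardization

Recording eligibility mirrors archive curation practice: quality grade
"A", duration > 30 s, vocalisation type containing song/call/drumming
and none of wingbeat/flap/begging/alarm/night (case-insensitive
substring matching), at most 50 files per species (uniform random subset
beyond that). If no file is long enough, the shorter quality/type-
compliant files are used instead, each stitched from repeats of itself
until it exceeds 30 s. Each surviving file keeps seconds [2.5, 27.5) —
the head is dropped because uploaders tend to start recordings just
before a vocalisation, and the first moments often carry handling noise
— is downmixed to mono by channel mean, resampled to 44.1 kHz
(polyphase FIR anti-aliasing), and peak-normalized to −6 dBFS
(linear 0.50119). "Normalized with a −6 dB gain" is implemented as peak
normalization to −6 dBFS, the reading that gives every source file a
consistent volume. Audio is stored as lossless WAV (float32 on disk,
float64 in memory); a lossy export stage would make index values
codec-dependent without touching the method's substance.

## Acoustic indices

One spectrogram serves all four indices: 512-sample frames, no overlap,
Hann taper, magnitude in dB relative to the matrix maximum (max = 0 dB).
A Hann window is used (rather than a rectangular one) because with the
−50 dB relative occupancy threshold, boxcar sidelobes (−13 dB first
sidelobe, ~6 dB/octave rolloff) from any strong narrowband song spill
above threshold across the entire 0–10 kHz range and saturate the
occupancy vector; the Hann taper (−31 dB, 18 dB/octave) keeps leakage
below threshold, and is what the standard R ecoacoustics implementations
default to. Exactly-zero magnitude cells are floored at −200 dB.

- **ADI / AEI** share the band-occupancy vector: 10 bands of 1000 Hz up
  to 10 kHz, occupancy = fraction of cells above −50 dB. ADI is the
  Shannon entropy of the occupancy vector normalized to sum 1 over
  occupied bands; AEI is the Gini coefficient
  `Σ_ij |p_i − p_j| / (2 n² p̄)`. An all-empty vector returns 0 for both
  (degenerate).
- **BI**: per-bin spectrum averaged across frames in the *power*
  domain (``10 log10(mean 10^(dB/10))``, the ``meandB`` convention of
  the reference R implementations — silence does not drag a bin's mean
  down, and growth is log-compressed), restricted to [2000, 22050] Hz,
  shifted so the in-range minimum is 0, summed and scaled by the bin
  width in kHz. The 22.05 kHz upper bound is the protocol's stated
  deviation from the usual default; the 2 kHz lower bound is kept and
  configurable.
- **H = Ht × Hf**: Ht is the Shannon entropy of the per-frame RMS
  amplitude envelope normalized by `log(n_frames)`; Hf the entropy of
  the per-bin mean linear magnitude spectrum normalized by
  `log(n_bins)`. The envelope is taken at frame resolution (from the
  same framing as the spectrogram, before tapering) rather than from a
  full-length analytic signal: it bounds the entropy support for
  arbitrarily long canvases, makes H a by-product of the shared
  spectrogram pass, and at 11.6 ms frames resolves every temporal
  feature the 25 s insertion protocol can create.

Silent input is a degenerate case, not an error: the index entry points
signal it, and the batch path records an all-zero flagged row (an empty
community produces a silent, warned-about soundscape).

Because dB values are relative and the entropies are normalized, all
indices are invariant to rescaling a canvas by any positive constant
(tested to 1e−9).

## Synthetic recording library

Each species gets a parametric song: syllables are linear frequency
sweeps (`f0 → f0 + bandwidth`, bandwidth 0.5–2 kHz) with 1–3 harmonics
at −6 dB per harmonic under a Hann envelope, repeated at period
`syllable_dur / duty_cycle` (duty 0.45–0.90) with a random phase
offset, so the voiced fraction of a file approximates the duty cycle.
Species carriers are an evenly spaced, shuffled ladder over
1.5–6.5 kHz — distinct carriers place different species in different
occupancy bands (making ADI/AEI respond to composition) while broad
sweeps and harmonics give substantial spectral overlap between species,
as real songbird communities have. Per-file jitter (carrier ±3 %,
syllable duration ±10 %) emulates between-individual variation.

Each file also carries the background of a field recording, whose level
profile matters for the threshold-based indices: (i) *colored ambient
noise* with a 1/f-sloped amplitude spectrum, peak-normalized to
0.01–0.03 — the smooth slope places some content near the −50 dB
occupancy threshold at every frequency, so band occupancy responds
gradually as individuals accumulate rather than switching on or off;
(ii) *soft background chirps* at random frequencies (~0.8–1.5 per
second, ~20 dB below the song peak), standing in for non-focal species,
which make all-band occupancy grow with the number of inserted
individuals; (iii) *faint wideband microphone self-noise* near the edge
of the 16-bit dynamic range, below the −96 dB spectrogram floor for a
lone recording, so the quietest spectral bins lift off the floor only
as sound accumulates. Without this background structure,
single-species soundscapes occupy only their own harmonic bands and the
indices lose the abundance responses that real archives show. Manifest
metadata (quality grade, vocalisation type, region) emulates archive
fields; by default 10 % of files are downgraded below quality "A" and a
small share get excluded vocalisation types, so the eligibility filters
have something to do.

What the generator does **not** emulate: real song complexity (trills,
frequency modulation patterns, species-specific rhythms), amplitude
differences between species, diel/seasonal vocal activity, or any
spatial structure in sound propagation. Consequently, absolute index
values from synthetic libraries are not comparable to values computed
from real archives — all tests and experiments here are about
directions, orderings and calibration, never about absolute index
levels.

## Synthetic count datasets

Sites sit on a regular lat/lon grid split into four quadrant strata.
Each site draws its own species ordering and its own multiplicative
yearly rates for richness and mean abundance — log-normal around the
design rates with spread `site_trend_sd`. In year *t*, realized richness
is the rounded latent trajectory (declines drop species in a stable
order, emulating turnover) and realized counts are zero-truncated
Poisson draws about the latent per-species abundance (count tables only
list detected species). Defaults (100 sites, 10 years, base richness 12,
base abundance 3) give site-year communities of a few dozen individuals,
typical of a point-count scheme. With both trends at 1 and
`site_trend_sd = 0` the expected totals are stationary, and the fitted
log-total year slope converges to 0 as sites grow (tested).

## Statistical stage

Standardization (per site, per metric: subtract the across-year mean,
divide by the across-year SD) uses `ddof = 1`; sites with fewer than 3
surveyed years or zero variance are dropped and reported. The whole
downstream stage is therefore invariant to per-site affine rescaling of
the raw indices (tested to 1e−12).

The continental model is a Gaussian LMM with fixed latitude, longitude
and year (covariates centred; slopes unchanged) and crossed random
intercepts for site, year, stratum, and route when route labels exist.
Fits maximize the ML (not REML) likelihood so that likelihood-ratio
tests between nested fixed-effect structures are valid; the chi-square
reference with 1 df is used, as is standard. The solver profiles out the
fixed effects and the residual variance analytically and optimizes only
the log variance ratios (Nelder-Mead from a fixed grid of starts), using
sufficient statistics so a likelihood evaluation costs O(q³) in the
total number of random-effect levels, independent of the number of
rows. It reproduces lme4's ML fits to 4–5 decimals on fixture data
(tested), and its null LRT for the year term is calibrated (~4–5 %
rejection at the 5 % level in Monte Carlo). Variance components hitting
the zero boundary are pinned at 0 with a warning. Categorical-year mode
replaces the slope with year dummies and returns per-year predictions;
latitude×year and longitude×year interactions are available in
continuous mode.

Site trends (z on year, OLS) require ≥ 3 years; their standard errors
feed the trend-on-trend bootstrap: each replicate redraws every
site-level trend from Normal(trend, SE), refits the association model
(index trend ~ individuals trend + species trend, stratum random
intercept, interaction kept only if its LRT p < 0.05 in the base fit),
and records per-term significance; the reported quantity is the
proportion of significant replicates. With all SEs zero the bootstrap
degenerates to the base model's indicator (tested). Pairwise Pearson
correlations over the four indices' site trends give the C(4,2) = 6
coefficient summary; zero-variance inputs are reported as missing.

The significance threshold is 0.05 throughout and no multiple-testing
correction is applied, matching the protocol this pipeline implements.

## Problem sizes used in tests and the acceptance script

Simulation experiments run at desk scale: the community grid uses a
20-species pool, richness {2, 5, 10} × abundance 1–10 × 25 iterations;
the construction-rule sensitivity experiment uses 50 communities of 10
species drawn from a 40-species pool (so community compositions barely
overlap, as when sampling from a continental pool), declining 10 → 5
over 6 years under four variants (5/3/10-min canvases with uniform
gains, 5-min with half-normal gains); the end-to-end run uses 100
sites × 10 years with mean 2 %/yr richness and abundance declines and a
between-site log-rate spread of 0.06 — under which roughly a third of
sites increase while the majority decline, the mixture real monitoring
schemes show — at 60 s canvases and 2 construction iterations; the
null-calibration check uses 200 replicates of 30-site × 12-year
panels; the bootstrap uses 200 draws. These sizes are the package's
chosen defaults for reproducible desk-scale experiments; the full-scale
protocol values (5-min canvases, 5 iterations, 1000
iterations/communities/draws) remain the library defaults for
production use.

## Known limitations

- The LRT chi-square reference is asymptotic; with very short panels
  (few years) the year test can drift from nominal size.
- Band occupancy, and hence ADI/AEI, depends on the spectrogram window
  through its leakage profile; results are comparable only across runs
  with the same window settings.
- BI on dB-relative spectrograms carries a baseline "fluctuation area"
  from any broadband noise floor; BI comparisons are meaningful between
  soundscapes built from the same library, not across libraries with
  different noise characteristics.
- The construction protocol treats every individual as one 25 s file
  per iteration; species-specific vocalisation frequency or duration is
  not modelled, and no distance-dependent attenuation, ambient layer or
  spatial audio is applied.
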