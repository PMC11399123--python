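# Methods

## Scope and model

`percepsim` implements a similarity-elicitation psychophysics pipeline in
which every data source is synthetic and fully specified, so each analysis
stage can be validated against known ground truth. The pipeline has three
arms:

1. **Similarity.** Repeated bounded pairwise ratings are generated from a
   latent Euclidean "psychological space", aggregated into a square
   similarity matrix, and analysed for structure: interval profiles and
   octave peaks on pitch ladders, classical MDS embeddings, upper-triangle
   correlations with bootstrap confidence intervals, and split-half
   inter-rater reliability.
2. **Confusion.** Row-stochastic confusion probabilities are converted to
   similarity scores via `s_xy = sqrt(p_xy p_yx / (p_xx p_yy))` and feed the
   same matrix analyses.
3. **Naming.** Forced-choice color-naming responses over the 330-chip
   WCS-style Munsell palette are reduced to dominant-term maps and compared
   across languages with the adjusted Rand index.

## Stimuli

* **Pitch.** Tones live on the semitone (MIDI) scale with
  `p = 12·log2(f/440) + 69`. The default ladder spans two octaves, C4
  (60; 261.626 Hz) to C6 (84; 1046.502 Hz), in 1-semitone steps — 25 tones.
  The harmonic-complex rendering of each tone (10 partials, 3 dB/octave
  roll-off) is metadata only; no audio is synthesised. A jitter control
  shifts every pitch by ±0.1 semitones (i.i.d. signs) to break alignment
  with integer note numbers while preserving ladder geometry.
* **Colors.** The default set is the classic 14 monochromatic wavelengths,
  434–674 nm. Hex codes come from an in-package piecewise-linear
  visible-spectrum approximation (380–780 nm, gamma 0.8). This is not
  calibrated colorimetry; only hue ordering and determinism matter here. The
  set can be extended (to 23 by default usage) by inserting midpoint
  wavelengths, widest gap first, ties broken toward the shorter-wavelength
  gap — a deterministic, order-independent rule.
* **Munsell palette.** 330 chips: 10 achromatic lightness levels (column 0)
  plus 40 hue columns × 8 chromatic rows. Chip hexes and 3-d coordinates
  (hue angle, unit chroma, lightness on a ×2-weighted axis) are synthetic,
  perceptually ordered stand-ins for calibrated Munsell renotation; the
  naming analyses depend only on the grid layout and ordering.
* **Consonants.** A symbolic 16-item IPA inventory (two speakers); no audio.

## Synthetic respondents

Respondents are generative stand-ins for human raters and language-model
APIs; their only contract is to carry a known latent structure through the
pipeline.

* **Similarity rater.** Rating = `clamp(exp(-d/tau) + ε, [0, 1])` mapped
  affinely onto the response scale, with `ε ~ N(0, noise_sd²)`; discrete
  (Likert) scales round to the nearest level. Defaults: `tau = 1`,
  `noise_sd = 0.05`, 10 repetitions per pair — matching the aggregate-of-10
  protocol of the similarity studies this emulates. Gaussian-then-clamp is a
  modelling choice made for analyzability; real raters are black boxes.
* **Pitch helix.** A tone at pitch `p` maps to
  `(r·cos(2πp/12), r·sin(2πp/12), h·p)` with radius `r = 1` and rise
  `h = 0.08` per semitone. Closed form:
  `d(s)² = (h·s)² + 2r²(1 − cos(2πs/12))`, so the octave (s = 12) is a
  strict local distance minimum versus s = 11, 13 whenever
  `h < 0.108·r`; at the defaults the profile contrast at the octave is
  ≈ 0.046, about 1.5× the next-largest contrast.
* **Hue circle.** Colors sit on a circle at their hue angles; radius 1.
* **Confusion generator.** Row x of the count matrix is multinomial with
  probabilities ∝ `base_similarity[x,·]^concentration`. Counts receive
  add-one smoothing before normalisation so diagonal probabilities are
  strictly positive (the similarity conversion divides by `p_xx p_yy`).
* **Naming respondents.** P(term | chip) is a softmax over
  `−d(chip, prototype)/temperature` with 15 fixed prototypes per language
  (hue, lightness, chroma constants shipped with the package). The Russian
  table splits the blue region by lightness into синий (dark) and голубой
  (light) and the violet region into фиолетовый and лиловый; English has
  single blue/violet categories there. Default temperature 0.15 yields
  realistic mixtures of unanimous and contested chips. Chips equidistant
  between two prototypes remain contested at any temperature — that is a
  property of forced-choice naming at category boundaries, not of the noise
  level.

All generators are deterministic under seeds. One root seed spawns
per-stage seeds keyed by stage name, so adding a stage never shifts the
streams of existing ones.

## Statistics

* **Aggregation.** Cell (i, j) is the mean of all ratings for the unordered
  pair; unrated cells are missing (NaN) and propagate; parse failures are
  excluded upstream and counted.
* **Smoothing / interval profile.** After symmetrization, each cell at
  separation `s = |i − j|` is replaced by the sub-diagonal mean, yielding a
  symmetric Toeplitz matrix; the profile reports the mean and pair count per
  separation (n − s pairs on an n-tone ladder). The octave peak is the
  interior separation maximising `c(s) = mean(s) − (mean(s−1)+mean(s+1))/2`,
  ties broken toward the smaller separation; the contrast is reported so
  callers can require `c > 0`.
* **Correlation.** Pearson r over the strictly upper triangle
  (self-similarities are never elicited, so the diagonal is excluded), over
  pairwise-complete cells, with the count reported. Correlation is
  affine-invariant, so 0–1 and 0–6 scales compare without normalisation.
* **Bootstrap CIs.** Percentile 2.5/97.5 over 1,000 rounds by default. For
  correlations, each round resamples every pair's repeated ratings with
  replacement and rebuilds the mean matrix; for ARI, each round resamples
  every chip's responses and rebuilds both dominant maps. *Known property:*
  both schemes are biased below the unresampled point estimate — rating
  resampling inflates per-pair noise (attenuating r), and resampling flips
  dominant terms on contested chips (degrading ARI) — so the raw percentile
  interval can exclude the point. Intervals are therefore widened to cover
  the point estimate, which then sits exactly at an interval edge in the
  biased regime; noiseless data still collapses to a zero-width interval.
* **Reliability.** Each round halves the rater pool at random, averages each
  half's matrix, correlates upper triangles, and applies the Spearman–Brown
  correction `2r/(1+r)`; the mean corrected value and percentile CI are
  reported. The consistency bonus for repeated catch trials is
  `min(max(0, 0.1·s), 0.1)` USD with s the Spearman correlation.
* **Classical MDS.** Similarities are converted to dissimilarities by
  min–max normalisation of the observed range (`d = (s_max − s)/(s_max −
  s_min)`, zero diagonal), squared, double-centered (`B = −½ J D² J`), and
  eigendecomposed; coordinates are the top-k eigenvectors scaled by the
  square roots of the nonnegative-clipped eigenvalues. Classical (Torgerson)
  MDS was chosen over stress-minimising variants for determinism. Recovery
  is quantified by the Pearson correlation of embedded vs true pairwise
  distance vectors, which is invariant to rotation, reflection, translation
  and uniform scale, so no explicit Procrustes alignment is required.
* **ARI.** From the contingency table: with `S = Σ C(n_ij,2)`,
  `SA = Σ C(a_i,2)`, `SB = Σ C(b_j,2)`, `a = C(n,2)`: `b = S`,
  `c = a − SA − SB + S`, `RI = (b+c)/a`,
  `RI_rand = (a + 2·SA·SB/a − SA − SB)/a`, `ARI = (RI − RI_rand)/(1 −
  RI_rand)` — algebraically identical to the standard
  hypergeometric-expectation form and verified in tests against brute-force
  O(n²) pair counting and an independent library implementation. Degenerate
  case: if `RI_rand = 1` (both partitions trivial) ARI is defined as 1.
* **Dominant maps.** Modal term per chip, ties broken lexicographically
  (determinism); agreement marks: "−" below 50%, "*" below 90%, unmarked at
  or above 90% (equality at a boundary closes upward). Legend colors average
  member-chip RGB channel-wise and re-quantize to hex.

## Numerical and protocol choices

* Delimited text is comma-separated UTF-8 with mandatory headers; floats are
  written with 12 significant digits, making write→read→write byte-stable.
* Prompt parsing takes the first decimal number (ratings) or the longest
  matching term (naming); malformed responses are typed failures excluded
  from aggregation with a reported count, never exceptions.
* In-context example pairs are fixed per dataset; a helper flags any target
  pair that coincides with an example pair so those cells can be audited.
* MIDI values are stored as reals (jitter produces non-integers).

## Problem sizes used in tests and the acceptance script

The default study conditions are used throughout: 25 tones × 10 repetitions
(300 pairs, 3,000 ratings) for pitch; 14 colors for the hue circle; 330
chips × 10 responses per language for naming; 1,000 bootstrap rounds. The
hue-circle MDS check uses a noiseless respondent with `tau = 5`: the
exponential kernel is near-affine in distance at that length-scale, and
classical MDS of affine-in-distance similarities reconstructs a circle
exactly, whereas at `tau = 1` kernel compression alone displaces embedded
points ~7% off a common radius.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers known structure
(octave spike at 12 semitones, helical pitch geometry, the hue circle, the
Russian blue/violet splits) from data generated under its own respondent
models, and that the statistics equal their formula definitions. They do
not certify anything about real human or language-model raters: the
respondents have no individual differences, no response drift, isotropic
Gaussian noise, and category prototypes chosen by construction. Results on
real data depend on those unmodelled factors.

## Known limitations

* Munsell chip colors are ordered stand-ins, not renotation colorimetry.
* Nonmetric MDS, correlation significance tests, and figure rendering are
  out of scope.
* Bootstrap intervals inherit the downward bias described above; widening
  to include the point makes the reported interval conservative on the side
  of the point but does not remove the bias of the percentile bounds
  themselves.
* The wavelength→hex approximation saturates at the red end (≥ 645 nm maps
  to pure red), so nearby long wavelengths can share a hue.
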