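# Methods

This note documents the model implemented by `stereoevo`, the defaults and
why they were chosen, what the synthetic environment does and does not
emulate, and the numerical and design decisions a maintainer should know
about.

## Model overview

The package tests whether depth can be decoded from *anatomical*
correspondence alone: retinal loci are paired by identical position in the
two eyes, and any surface off the horopter then produces unequal activity
in the paired monocular units — the contralateral projection of a far
surface is displaced eccentrically, the ipsilateral one foveally, and vice
versa for near surfaces. Evolved downstream circuits read this activity
difference as signed depth. No image matching, cross-correlation, or
phase/position-shift energy computation is involved anywhere.

The pipeline has four fixed stages:

1. **Stimulus world** — seeded banks of stereo pairs (absolute-disparity,
   relative-disparity, position-randomised control; conventional or
   anti-correlated).
2. **Monocular front end** — fixed ON-centre/OFF-surround units at
   anatomically corresponding positions.
3. **Evolvable network** — second-order (absolute) and third-order
   (relative) binocular units, each a sum of four signed-logistic
   connections.
4. **Evolution and probes** — a roulette-selection genetic algorithm and
   physiology-style measurements on the evolved genomes.

## Stimulus world

Geometry: 200 × 40 sensors per eye, 0.01°/pixel, spanning ±1° azimuth;
azimuth is negative left of the midline, and because the target sits in
the left visual field the left eye is labelled *contralateral*
(right-hemisphere convention). Luminances: figure 400 cd·m⁻², background
1 cd·m⁻².

Each strip is parameterised by the azimuth of its defining vertical
contrast edge and extends foveally (rightward) from it. The fixation strip
spans [0°, 0.3°]; the target edge sits at −0.3°, the optional reference
edge at −0.6°; variable-depth strips are 0.15° wide (configurable). This
orientation is deliberate: it makes far disparity *increase*
contralateral-unit activity (the strip slides onto the ON centre) and
decrease ipsilateral activity, which is the sign convention under which
far-tuned units should evolve contralateral excitation. With the strip
extended eccentrically instead, both relationships — and hence every
evolved sign — would flip.

Disparity is parameterised directly in degrees of visual angle (metric
depth and interocular distance are redundant for the training signal) and
split symmetrically, ±d/2 per eye. Sub-pixel edge positions are rendered
by exact area-weighted anti-aliasing of the edge column, so disparity is
continuous despite the pixel grid. Overlapping strips (possible only in
extreme relative-disparity configurations) are merged as a union before
rasterisation. Scenes are uniform vertically, so pairs store one luminance
row per eye and broadcast to full images on demand; the two code paths are
tested to be bit-equivalent.

Banks: absolute banks draw |d| uniformly on (0, 0.18°] with the sign fixed
by polarity — 0.18° is half the receptive-field width, the classical
upper bound for unambiguous matching, and the training distribution is our
choice since no distribution of depths is prescribed. Relative banks draw
target and reference disparities independently and uniformly on
[−0.18°, 0.18°] and rejection-sample the required sign of
target − reference, which realises all three depth-configuration classes
(both-far : straddle : both-near in expectation 1 : 2 : 1). Control banks
additionally draw the target azimuth uniformly over the interval that
keeps every displaced edge ≥ 0.18° from the array border.

Anti-correlation inverts one eye's profile about the luminance mid-level
(figure ↔ background; anti-aliased edge mixtures invert linearly), leaving
labels untouched; applying it twice restores the pair. Probes default to
inverting the contralateral eye; for near-polarity units the scientifically
matched probe inverts the ipsilateral eye instead, i.e. the eye feeding the
polarity's dominant excitatory line.

## Monocular front end

Each unit: 36 × 36 pixels (0.36°), 3 × 3 grid of 12 × 12 subregions, ON
centre, eight OFF surrounds. Subregion drive = block mean luminance /
figure luminance (sigmoid constants are only meaningful on a bounded
drive). Per-subregion sigmoids are preset; the published source for their
exact values is not recoverable, so the defaults are stand-ins chosen for
function: centre (A 1.0, B 6.0, C 1.5, +), surround
(A 0.125, B 6.0, C 1.5, −). The surround gain is one eighth of the centre
gain so the eight OFF blocks exactly balance the ON centre: a uniform
field yields zero net drive. With surround gain equal to centre gain
(an earlier candidate default) the pre-output sum is ≤ 0 for every
stimulus and the output sigmoid pins all activities at ~10⁻⁴ — a
non-functional front end; balance is the minimal repair that preserves the
ON/OFF structure. The output sigmoid (A 0.9771, B 5.7152, C 1.7300) is the
published value.

The printed transfer-function formula is typographically ambiguous; it is
read as the standard logistic ±A/(1 + e^(−B·pre+C)), with the ± carried as
a discrete sign so excitatory/inhibitory classification is well defined.

One consequence of 0.15°-wide strips with 0.3° unit spacing: the target
strip's trailing edge reaches into the fixation pair's OFF surround, so
the fixation-pair activities carry a (weaker) copy of the disparity
signal. This crosstalk is physical — any surface wider than 0.03° must
overlap a neighbouring field — but it gives evolution an alternative route
to ipsilateral-eye information, and evolved populations sometimes place
their inhibition on `ipsi@fixation` instead of `ipsi@target` (see
Limitations).

## Evolvable network and genetic algorithm

A genome holds four connections (gain A ≥ 0, slope B, offset C, sign ±1);
the unit response is the plain sum of the four sigmoid outputs and is read
as disparity magnitude in degrees. Polarity lives in the network's
identity: far/near (and rel_far/rel_near) units evolve separately against
|label|, which keeps every training target non-negative and matches the
separate-evolution protocol.

Initialisation ("weak but fully connected"): A ~ U(0, 0.1),
C ~ U(−5, 5), sign equiprobable. Slopes scale with the stage's input
scale: B ~ U(0, 10) for second-order units (monocular activities are
order-one) but B ~ U(0, 100) for third-order units, whose inputs —
second-order responses — are disparity-coded and an order of magnitude
smaller; with B ≤ 10 a third-order sigmoid is confined to an almost
linear, shallow sliver of its range and the stage cannot express the
required mapping.

Per generation and population: a fresh seeded 200-stimulus bank (the
source does not state whether stimuli were re-drawn; re-drawing avoids
overfitting a single bank and keeps every generation i.i.d.); lifetime
error Σ|response − disparity| per individual (monocular activities are
computed once per bank and shared — a bit-equivalent optimisation);
success scores = max error − own error, with a uniform fallback when all
errors tie (the printed fitness formula is internally inconsistent, and
this is the simplest monotone realisation of "sector proportional to
success"); roulette selection by cumulative sums with half-open sectors
(boundary to the higher index); parameter exchange — each individual, with
probability 0.8, pairs with a uniformly chosen other individual and swaps
each scalar parameter with probability ½ (conserving the population-wide
parameter multiset exactly); finally Gaussian mutation, probability 0.02
per parameter, s.d. 5% of the parameter's init range, clipped to bounds
(gain [0, 1] — above the init range so strong connections can emerge by
drift; slope and offset at their init ranges), signs flipping with the
same probability. Mutation exists because pure exchange can never create
values absent from the initial gene pool; it is switch-off-able
(`mutation_probability=0`). There is no elitism.

Reproducibility: per-population seeds derive from the master seed via
`numpy.random.SeedSequence(master_seed).generate_state(n) mod 2³¹`; each
population's generator then yields its per-generation bank seeds, so any
bank and any run can be regenerated bit-identically from the config alone.

Problem sizes: the full-scale configuration is 20 populations × 500
networks × 2,500 generations; the package's standard reduced setting
(`EvolutionConfig.desk()`, used by the test suite and the acceptance
script) is 5 × 200 × 600, chosen as the smallest scale at which the
qualitative connectivity and tuning phenomena are stable across seeds.

## Probes

* **Tuning curves** — render each probe disparity (third-order relative
  disparity r realised as the symmetric combination target = +r/2,
  reference = −r/2), forward-pass each population's best genome, aggregate
  mean ± s.d. across populations.
* **Disparity limit** — the largest probed |d| (0.01° grid to 0.18°) at
  which the median absolute response error across populations stays within
  0.02°. Operational definition of ours; no formula is prescribed for the
  published ~0.14° figure.
* **Ocular dominance** — response-based, not weight-based (evolved
  nonlinearities make raw gains incomparable): sweep the target edge
  ±0.09° monocularly with the other eye at uniform background;
  ODI = (M_c − M_i)/(M_c + M_i) on peak-to-trough modulations, 0 with a
  degenerate flag if both modulations vanish.
* **Connection classification** — per-connection output swing over a
  conventional disparity sweep; swing < 1% of the unit's total response
  range ⇒ negligible, otherwise the connection's sign decides
  excitatory/inhibitory.
* **Depth preference** — disparity of maximal response on the conventional
  curve (one reasonable choice; used for the dominance–tuning
  correlation, computed as a standard Pearson r).
* **Retinotopy verdict** — a run "evolved" only if its final median error
  beats 0.8 × the best-constant-predictor baseline (the median training
  disparity) on its own evaluation banks; otherwise "failed".

## What the generator does and does not emulate

The environment is minimal by design: two (or three) luminous vertical
strips, no texture, no vertical disparity, no occlusion, no temporal
dynamics, no random-dot stereograms, and a single fixed fixation distance.
Passing tests therefore show that the anatomical-correspondence code is
learnable and produces the right circuit signatures *in this reduced
world*; they do not show robustness to natural images, cluttered scenes,
or stimuli without a luminance-defined edge. The horizontal extent of the
depth-varying surfaces is not recoverable from the source; fixed-width
strips are a stand-in, and the strip width (0.15°) trades off driving the
target unit well against leaking into the neighbouring field.

## Known limitations

* The fixation-pair crosstalk described above means the textbook
  connectivity signature (inhibition specifically from `ipsi@target` in
  far-tuned units) emerges in only a fraction of populations; the
  functional pattern (contralateral excitation, ipsilateral-eye
  inhibition through one path or the other) is robust.
* The monocular code saturates once the target edge leaves the 0.12° ON
  centre, so evolved response ranges top out near the disparity limit
  (~0.12°) rather than at the 0.18° training maximum; correspondingly the
  upper end of the conventional response range lands somewhat below the
  published 0.15.
* Anti-correlated probes produce strongly attenuated curves and reverse
  the tuning slope, robustly for far-tuned units and more weakly (and
  seed-dependently) for near-tuned ones: single-eye contrast reversal
  leaves the unflipped eye's in-distribution drive intact, which can mask
  the reversal and keeps many anti-correlated responses slightly positive
  rather than mostly negative.
* The third-order stage converges to a few hundredths of a degree of
  relative-disparity error at desk scale — clearly better than a constant
  predictor, with the expected antagonistic connectivity — but the pure
  roulette + exchange algorithm stays well above the stage's
  representational ceiling (~0.016° by direct optimisation of the same
  parameterisation).
* With subregion parameters being stand-ins, quantitative agreement with
  published magnitudes is approximate wherever it depends on the exact
  monocular transfer function.
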