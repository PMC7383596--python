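# Methods

## The model

`phasegrid` simulates a population of medial-entorhinal grid cells whose
spiking combines a spatial **rate code** with a temporal **phase code**
referenced to a baseline oscillation, and asks what can be decoded from that
activity — in particular when the baseline has no stable rhythm.

The firing rate of a cell at time *t* factorizes as

    r_g(t) = r_x(x(t)) · r_φ(φ(x), θ(t))

with

- **rate code** `r_x(x) = r_c · exp(−d² / 2σ_m²)` where *d* is the distance
  from the agent to the nearest node of the cell's triangular lattice
  (60° rhombic basis, scale *s_m*), σ_m = s_m/10, and r_c is the per-field
  peak rate (1 everywhere in uniform mode; independent draws from a
  rectified Normal(1, 1), fixed for the session, in heterogeneous mode);
- **phase code** `r_φ = exp(k · cos(φ(x) − θ(t)))`, a circular Gaussian
  around the location-dependent preferred phase, with concentration
  k = 1.5 (circular SD ≈ 0.9 rad);
- **preferred phase** `φ(x) = 2π (d_φ/s_m + ½)` in precession mode, where
  `d_φ = v̂ · (x_c − x)` is the distance to the nearest node projected onto
  the travel direction — so phase sweeps one full cycle earlier per field
  traversal and equals π at the field centre; in locking mode φ = π
  everywhere.

The overall drive is `R(t) = r_g(t) · f(t) · m_v · v(t)` with m_v =
0.16 cm⁻¹: the instantaneous baseline frequency factor normalizes spikes
per oscillatory cycle, and the speed factor reproduces the empirical
rate–speed relation. Spikes are drawn from an inhomogeneous Poisson
process with rate `r_tot = r̄ T · R / ∫R dt`, so every cell has an expected
session-mean rate of r̄ = 2 Hz; the normalization integral runs over the
full session including sub-threshold-speed samples. The default
population is N = 200 cells in 5 modules, scales 30 · 1.4^m =
{30, 42, 58.8, 82.32, 115.25} cm, with spatial offsets uniform over one
lattice unit cell and module orientation 0° (configurable).

Because a traversal advances `d_φ` one-to-one with distance travelled, the
intrinsic burst frequency of a precessing cell exceeds the baseline by
`v/s_m` — positive for all cells, proportional to running speed, and
inversely proportional to grid scale.

## Synthetic study conditions

The reference data (depth-electrode LFP, foraging trajectories) are not
distributable, so generators emulate them. Their defaults define the
study conditions and are not tuned per analysis.

**Trajectories.** 1D: running speed is a Gaussian-increment random walk
reflected into [2, 30] cm/s (decorrelation ≈ 1 s), integrated to position;
300 s gives a ~50 m track. 2D: the same speed process with a heading that
diffuses as angular Brownian motion (decorrelation ≈ 1 s), folded into a
1 m box by billiard reflection (preserves step lengths, mirrors headings).
A 300 s session covers ~65% of 2-cm bins — full coverage is geometrically
impossible at these speeds (≤ 9000 cm of path for 2500 bins), so unvisited
bins are masked throughout rather than zero-filled.

**Baseline signal.** The rodent condition is a pure 8 Hz sinusoid. The
arrhythmic condition is a frequency-modulated oscillator whose
instantaneous frequency performs a reflected random walk on
**log-frequency** across 2–20 Hz (decorrelation ≈ 1 s): log-uniform
occupancy gives equal power per octave, i.e. the 1/f-weighted,
low-frequency-dominated spectrum characteristic of hippocampal LFP, with
no narrow spectral peak (mean instantaneous frequency ≈ 7.5 Hz). A slow
positive amplitude envelope (depth 0.5, ~2 s decorrelation) and a 1/f
background at 0.3 relative amplitude make the trace realistic; both are
removed by the phase-extraction step. What these generators do **not**
emulate: non-stationarities (drowsiness, epochs of immobility theta),
artifacts, and any coupling between LFP frequency and behaviour — so
passing tests show the analyses behave correctly under the model's
assumptions, not that real recordings will be as clean.

**Phase extraction.** Band-pass 2–20 Hz (zero-phase second-order
Butterworth), Hilbert-transform phase, instantaneous frequency from
per-sample phase increments — clamped at zero, since the analytic phase of
a broadband signal can locally regress — smoothed with a 50 ms boxcar, and
both linearly interpolated to the 5 ms simulation clock. The first and
last 0.5 s are flagged and excluded from spike-phase analyses (filter and
analytic-signal edge artifacts). Phase lookups at spike times interpolate
the unit phasor between samples; nearest-sample lookup would add ±0.13 rad
of quantization jitter per spike, enough to destabilize the razor-thin
margins of shuffle tests against near-periodic references. For the same
reason the rate model is driven by the mid-bin phase, keeping spike phases
unbiased around the preferred phase (a bin-start convention biases them by
π · dt · E[f²]/E[f] ≈ 0.17 rad).

## Cycles and decoding

An **oscillatory cycle** is one full 2π revolution of the extracted phase.
Boundaries are the upward crossings of the oscillation **peak** (θ = 0).
This choice matters: firing concentrates at the trough (preferred phases
centre on π), so peak-to-peak cycles hold each population burst intact and
population activity dips between cycles; trough-referenced boundaries
would split bursts and reverse the within-cycle decoded location sweep,
sending direction decoding to ~180° errors. Cycles with mean running
speed < 5 cm/s are excluded from analysis, as are all sub-threshold
samples and spikes ("movement" filtering).

Per-cycle population vectors count each cell's spikes per cycle and per
phase bin. The five phase bins are quantiles of the session-pooled spike
phases measured from the cycle boundary, applied identically to every
cycle — equal pooled counts cannot hold per cycle with ~50 spikes.

- **Speed** is decoded by a linear fit of cycle-mean speed on total
  population count, trained on even-indexed movement cycles and evaluated
  on odd-indexed ones. Because the drive includes the f(t) factor, counts
  per cycle track speed rather than cycle duration.
- **Location** is decoded per cycle by Poisson maximum likelihood over
  2-cm bins in the log domain (no factorials), with expected counts
  `λ = rate map × mean cycle duration`. The decoder's rate maps come from
  the model's rate code evaluated at bin centres and normalized
  (movement-occupancy-weighted) to the 2 Hz session mean — mirroring the
  generative normalization. An expected-rate floor of 1e-6 Hz keeps
  log-likelihoods finite; argmax ties break to the smallest index. Errors
  ≥ 50 cm are counted as catastrophic.
- **Cycle identity** (location via "which cycle produced this vector") is
  decoded from the N × 5 per-phase-bin vectors against model-derived
  expectations per candidate cycle, either rate+phase or rate-only, and
  either informed of the true per-field peak rates or naive (r_c := 1).
  The candidate set includes the test cycle, since expectations are
  model-derived rather than observed.
- **Movement direction**: location is decoded independently in each phase
  bin (expected counts use that bin's mean duration); decoded x and y are
  regressed on bin index, and direction is the arctangent of the two
  slopes. The true direction is computed identically from the actual mean
  positions in the same usable bins. Bins with no spikes are excluded;
  cycles with fewer than three usable bins, or zero decoded displacement,
  are excluded and counted.
- **Auxiliary variable**: z = (f − 2)/18 encodes instantaneous frequency
  on [0, 1]; its per-cycle mean is recovered from cycle duration by
  alternate-cycle linear regression on the **inverse** duration (the
  per-cycle frequency), which linearizes a frequency-encoded variable.
  Regressing on raw duration instead leaves the 1/x curvature in the
  residuals and roughly triples the error.

## Analyses

**Rate maps** use 2-cm bins; spike counts and occupancy are smoothed with
a five-bin boxcar before division. **Fields** are 8-connected components
above 10% of the map peak with ≥ 5 (1D) or ≥ 10 (2D) bins; per-field peak
rates give the coefficient of variation. **Spatial autocorrelograms** are
Pearson correlations at every lag over the overlapping valid bins (≥ 20),
computed with masked FFTs. **Gridness** is min(correlation at 60°, 120°) −
max(30°, 90°, 150°) on an annulus from the central-peak edge (contour at
autocorrelation 0.3) to 1.25× the median radius of the six nearest peaks
(both radii configurable; fewer than six peaks falls back to a wide
annulus and flags low confidence); grid scale is the median six-peak
radius. Significance compares the true score with the 99th percentile of
100 surrogates that rotate the spike train relative to the *tracking* by a
uniform shift in [1, T−1] s.

**Phase locking** is the resultant length of movement-period spike phases
against the 99th percentile of surrogates that rotate the spike train
relative to the *LFP* (movement selection, a spike-vs-tracking property,
is fixed before shuffling). A caveat discovered here: against an exactly
periodic reference whose period divides the session length, a circular
time shift rotates every phase by a constant, the resultant is invariant,
and the test is degenerate — no shuffle can ever be beaten. Any
incommensurate session length breaks the degeneracy only marginally (the
wrap seam mixes two phase offsets), leaving near-ties that make the
outcome depend on shuffle count and tie-breaking. The test is well-posed
exactly when the reference frequency wanders, which is the regime this
package targets; results under the strictly-constant-frequency condition
should be read with that in mind.

**Oscillation index**: the ±2 s, 10 ms autocorrelogram (zero-lag bin
replaced by the maximum) is fitted with a decaying cosine plus slow
exponential, burst Gaussian and offset; bounded least squares from
uniform-random restarts (500 in principle; 30–100 suffice in practice and
are the desk default), keeping the best R². OI = a/max(A). For a rate
2(1+cos 2π·8t) train the exact-fit OI is 1/3; finite-data fits land
around 0.2 because the broad terms absorb part of the envelope.

**Precession** pools (phase, distance-through-field) spike pairs over
traversals; distance is the projection onto the entry-to-exit chord of
each traversal, normalized to [0, 1] (chords shorter than 4 cm are
dropped). Significance shuffles the phase–distance pairing (p =
(1 + #{|ρ_shuf| ≥ |ρ|})/(1 + n_shuf)); the slope is fitted by maximizing
the resultant of phase residuals over a dense slope grid (±2 cycles per
range, with local refinement), and ρ is the circular–circular coefficient
at the fitted slope, signed by the slope. Note that empirical
distance-through-field estimates attenuate the recovered slope by 20–30%
through errors-in-variables in the field-centre reference; with the
generative lattice geometry the slope recovers to within a few percent.

**Detection without rhythmicity**: spike-triggered averages of the
amplitude-normalized synthetic signal cos θ(t), split by early/middle/late
thirds of normalized traversal distance (window ±0.25 s). Using cos θ
makes the method exactly invariant to any positive amplitude envelope of
the raw signal. **MUA substitute**: summed population rate, causally
band-pass filtered (2nd-order Butterworth 2–20 Hz), correlated with the
synthetic signal; since the population bursts at the trough, the
comparison is against −cos θ by default, and the correlation is also
maximized over ±100 ms lags to absorb the causal filter delay.

## Problem sizes and numerical choices

Headline quantities are computed at the full population size (200 cells,
300 s sessions) over five replicate runs, with 100 surrogates for
gridness, 200 for phase locking and 200 for precession shuffles — chosen
as the package's reproducibility defaults. All randomness derives from a
single master seed through `numpy` SeedSequence spawning; identical seeds
give byte-identical outputs. Degenerate inputs (zero rate integral,
constant regressors, empty cycles) raise informative errors rather than
returning silent NaNs.

## Known limitations

- Gridness of the largest module (115 cm scale) is unmeasurable in a 1 m
  arena: its six autocorrelogram peaks lie beyond the observable lag
  window and its unit cell exceeds the arena area. Population
  significance percentages therefore saturate near 80–85%, with modules
  1–3 at ~100%.
- The shuffle test for phase locking is degenerate under a strictly
  periodic baseline (see above).
- Synthetic trajectories and LFP are stationary by construction; none of
  the analyses here have been validated against non-stationary or
  artifact-laden recordings.
- Conjunctive head-direction coding, place cells, and mechanistic models
  of precession (oscillatory interference, attractor dynamics) are out of
  scope; the decoding results transfer to place-cell codes in principle
  but are only demonstrated for grids.
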