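# Methods

## Passive model and units

All electrical computation assumes a purely passive membrane with uniform
specific properties: capacitance Cm = 0.9 µF/cm², membrane resistance
Rm = 20 000 Ω·cm² (membrane time constant τ_m = 18 ms), axial resistivity
Ri = 150 Ω·cm by default and varied over 100–200 Ω·cm where a range is
explored, leak reversal −70 mV (equal to the holding potential, so the cell
rests at the clamp level), synaptic reversal 0 mV.  Internally the solver
works in µm, ms, mV, µS, nF and nA; the cgs-style boundary units above are
converted explicitly at model construction.  These are the standard passive
parameters for molecular-layer interneurons; none of them is fitted by this
package.

## Discretization

The soma is a single isopotential spherical compartment of area π·d² —
adequate because a sphere has no internal axial resistance and, under an
ideal somatic clamp, soma size does not influence the clamp current (a
property verified by test).  The default idealized cell uses an 8 µm soma;
9 µm is available by argument where the three-dendrite variant is wanted.
Dendritic edges become chains of cylinders no longer than 1 µm (default).
Axial conductance between neighboring compartment centers composes the two
half-cylinder resistances 2·Ri·Δx/(π·d²); the soma contributes none.
Dendrites attach at the soma surface through an explicit attachment node,
so dendritic path distance is measured from the soma surface and the soma
interior carries no cable.

## Time integration

The tree system C·dV/dt = −A(t)·V + b(t) is advanced with Crank–Nicolson;
the first step is backward Euler to damp the ringing that CN exhibits at a
conductance-onset kink.  Each step solves the symmetric tree-structured
linear system directly in O(n) by leaf-to-root elimination in an ordering
where every parent precedes its children (the standard branched-cable
elimination).  An ideal voltage clamp is a Dirichlet condition at the soma;
the clamp current is the sum of membrane and axial currents at that node.
A series-resistance clamp instead couples the soma to the command potential
through a pipette conductance 1/Rs.  Divergent integrations (non-finite or
absurd voltages) raise an error suggesting a smaller dt.  Defaults
dt = 0.005 ms and Δx = 1 µm change the simulated quantal EPSC peak by less
than 0.5 % when both are halved (verified by test).  The solver is verified
against three independent routes: a dense stiff ODE integration of the same
equations (agreement to <0.01 % on the peak), the sealed-cable steady-state
closed forms cosh((L−x)/λ)/cosh(L/λ) and R_∞·coth(L/λ) (within 1 %), and
the analytic frequency-domain transfer function of a killed-end/sealed-end
cable in the small-conductance limit (within 0.5 %).

## Synaptic conductance

Quantal conductances are unnormalized differences of two exponentials
g(t) = Gmax·(e^(−t/τ1) − e^(−t/τ0)).  Peak time and peak value have closed
forms; the half-width is found by bracketed root finding on the continuous
waveform.  With the immature parameters (0.073/0.26 ms, 0.004 µS) the peak
is 0.00175 µS at 0.129 ms and the half-width 0.361 ms; the adult set
(0.072/0.24 ms, 0.0032 µS) peaks at 0.00134 µS with half-width 0.342 ms.
The analytic continuous-waveform 10–90 % rise times (0.0718/0.0693 ms) are
a few percent faster than values measured on coarsely sampled grids, so
peaks and half-widths, not rise times, are the precise anchors.

## Measurement conventions

Event analysis mirrors standard whole-cell practice: baseline is the mean
over the 1 ms before onset; the reported amplitude is the mean over a
100 µs window centered on the peak; 10/90/50 % crossing times are linearly
interpolated.  Two deliberate refinements make these measurements unbiased
on noisy data while exact on clean waveforms:

* the peak is located on a copy smoothed over 0.1 ms and refined to the raw
  argmax within the smoothing neighborhood — a raw global argmax would be
  displaced systematically by noise on slow events;
* the crossing levels anchor on a local parabolic (quadratic least-squares)
  estimate of the peak over the same 100 µs window, because the raw sample
  maximum overestimates a noisy peak (biasing half-widths short) while the
  windowed mean underestimates a sharp clean peak by ≈2 % (biasing
  half-widths long).  The parabolic estimate is exact for smooth waveforms
  and unbiased under additive noise.

τ_decay is the integral of the baseline-subtracted current from its peak to
its first return to baseline (or a 10 ms window end when the tail never
crosses, which otherwise leaves the integral ill-defined on noisy data),
divided by the peak; for a single exponential it equals the time constant.

Detection uses threshold crossing at `threshold_sd` (default 4) times the
robust noise SD (median absolute deviation, scaled) of the raw trace, with
the detection statistic boxcar-smoothed over 0.2 ms and a 2 ms dead time.
Smoothing is what keeps the false-positive rate below one per tens of
seconds at 100 kHz sampling — without it, single-sample noise excursions
cross any 4 SD amplitude threshold thousands of times per minute.

Kinetics of small miniature events at realistic signal-to-noise are
conventionally measured on the aligned average event (per cell), where
noise is suppressed by √n; `average_events` implements that, and the
parameter-recovery tests use per-event measurement for amplitudes and the
average event for kinetics.

## Protocols

Distance sweeps place one synapse per run at the dendritic compartment
whose center is nearest the requested path distance from the soma/dendrite
junction (ties distal), simulate an ideal somatic clamp, and measure the
baseline-subtracted clamp current.  The paired-pulse protocol injects two
conductances at one site, the second scaled 2.25× at a 20 ms interval, and
measures the second amplitude from the decayed tail; at an ideally clamped
soma the ratio is exactly 2.25 because the clamp current is linear in the
conductance at fixed voltage, while dendritic sites fall below it through
the loss of local driving force.  Input–output curves scale the unit
conductance by a quanta count under current clamp; the linear reference is
the response to 0.1 quanta, a conductance small enough that voltage is
linear in it.  The dendritic-sublinearity index normalizes each site's
somatic EPSP to its own per-quantum reference response and reports
1 − (normalized dendritic / normalized somatic).

The index is 0 for identical curves, lies in [0, 1) for passive models, and
grows with quanta while the somatic response is still near-linear.  It is
*not* monotone over arbitrarily large conductances: once the soma itself
saturates toward the synaptic reversal potential, both sites converge and
the index rolls off (in the immature configuration this happens above
roughly 5–10 quanta).  The per-site sublinear deficit
(linear_sum − peak)/linear_sum is monotone throughout and is the quantity
tested for monotonicity.

The mean miniature EPSC is synthesized as the pointwise weighted average of
per-bin quantal EPSC traces, with 10 µm distance bins represented by their
centers (the soma bin by the somatic quantal EPSC).  Because the per-bin
measured distributions and reconstructed morphologies behind the published
figure-level means are not available, the synthesis is validated
structurally: delta weights reproduce the somatic trace, equal weights the
pointwise mean, the synthesized amplitude is bounded by the somatic and
most-distal amplitudes, and shifting weight mass distally makes the
synthesized event smaller and slower.

## Puncta mapping

Candidate spots are accepted only if strictly larger than the imaging PSF
(default FWHM 0.3 × 0.3 × 1.1 µm) on *all three* axes — the conservative
per-axis reading of "larger than the PSF" — and strictly brighter than the
background mean + 3 SD.  Somatic puncta additionally require a soma-channel
intensity above half the stack maximum.  Skeleton branches are resampled at
100 nm arclength intervals (including branch start and terminus); each
branch's path distance continues from its attachment point, with primary
branches starting at 0 at the soma surface.  A punctum is assigned to the
nearest sample whose distance is within (local dendritic radius + α),
α = 0.2 µm (≈ the half-width at half-maximum of the lateral PSF), matching
an exhaustive all-pairs search by construction (KD-tree accelerated, oracle
verified in tests).  Distance histograms use half-open 10 µm bins; the
linear density divides puncta counts by (segment count × 0.1 µm), and the
per-segment ratio is also reported since the two differ only by that
factor.  Cumulative curves are sampled at 1 µm; two-sample comparisons use
the Kolmogorov–Smirnov test on raw distances; Pearson's median skewness is
3·(mean − median)/SD with the n−1 sample SD.

## Synthetic generators

The generators provide every stage with inputs whose ground truth is known,
and their defaults encode the published group statistics of immature vs
adult stellate cells; a seeded configuration reproduces its output
bit-for-bit.

* **Morphology**: five primary dendrites at both ages (primary count does
  not change with maturation); immature trees grow to ≈60 µm maximal path
  length with a branch probability of 0.025/µm, adult trees to ≈90 µm at
  0.02/µm, giving adults more branch points, longer maximal dendritic
  length and roughly 1.8× the total dendritic length — the drivers of the
  distal shift in the adult synapse distribution.  Dendritic diameters draw
  from truncated normals around 0.47 µm (immature) and 0.41 µm (adult).
  Branch order is capped at 4 to keep tree size in the biological range.
* **Puncta**: a homogeneous Poisson process along arclength at 0.46/µm
  (both ages — density is uniform and age-invariant; the age difference in
  counts comes from tree length), radially displaced by at most the local
  radius + 0.1 µm so every true punctum is recoverable within the search
  radius; 20 % decoys violate either the size or the intensity criterion to
  exercise the filters.
* **Recordings**: Poisson event trains (1.37 Hz immature, 1.14 Hz adult) of
  inward biexponential currents with amplitudes 48 ± 7 pA (immature) and
  24 ± 4 pA (adult) and time constants chosen so the measured 10–90 % rise
  and τ_decay equal the published 0.16/0.68 ms and 0.24/1.31 ms
  (τ0/τ1 = 0.177/0.503 and 0.217/1.093 ms), plus white Gaussian noise at
  SNR 10 (4.8 / 2.4 pA), sampled at 100 kHz.
* **Line profiles**: Gaussians whose FWHM equals the requested diameter,
  with optional additive noise as a fraction of the peak.

What the generators do *not* emulate: correlated (colored) recording noise,
event-amplitude/kinetics correlations, tapering diameters, tortuosity-vs-
Euclidean discrepancies in real reconstructions, PSF anisotropy in the spot
shapes, and clustered (non-Poisson) synapse placement.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical models, not robustness to every property of real data.

## Problem sizes

The test suite and the acceptance script run the simulations at the sizes a
desk check needs: the idealized cell discretizes to 91 compartments at
Δx = 1 µm and simulations span 8–15 ms at dt = 0.005–0.02 ms; Monte-Carlo
checks use 80 trees per age group, a few hundred puncta per tree, and tens
of seconds of synthetic recording.  All are chosen so the full suite
completes in a few minutes while leaving every statistical check
well-powered.

## Known limitations and documented discrepancies

* **Distance-filtering ratios.**  Under the stated conditions (ideal
  somatic clamp, 8 µm soma, one unbranched 90 × 0.47 µm dendrite, Ri
  150 Ω·cm, immature conductance at 45 µm) this implementation yields a
  ≈62 % amplitude reduction with rise and half-width at ≈238 % and ≈214 %
  of somatic, rather than the published 48 %/195 %/180 %.  The solver is
  verified against an independent dense ODE integration and the analytic
  cable transfer function; the published amplitude ratio coincides with the
  *linear* (vanishing-conductance) prediction, whereas the stated 0.00175 µS
  conductance produces a ≈19 mV local depolarization whose driving-force
  loss deepens the attenuation.  No combination of series resistance
  (0–20 MΩ), grid, or time step reproduces the published trio from the
  stated parameters, and the ideal-clamp somatic amplitude (122.5 pA)
  likewise exceeds the published simulated-somatic scale, indicating
  unstated elements in the original simulation pipeline.  The package
  reports its computed values unchanged.
* Of the published 1 kHz space-constant pair (46 and 60 µm over the Ri
  range), only 46 µm follows from the simplified high-frequency expression
  (45.6 µm at Ri = 200 Ω·cm); the other endpoint evaluates to ≈64.5 µm at
  Ri = 100 Ω·cm, so the 60 µm value is not used as an anchor.
* Active conductances, NMDA receptors, gap junctions, temperature
  corrections and stochastic channel noise are out of scope; the model is
  strictly passive.
* SWC dialects with multi-node somata are read, but the soma is always
  reduced to a single isopotential sphere at the root.
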