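# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `nigranet`. Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## The pacemaker neuron model

SNr projection neurons fire tonically (10–40 Hz) without synaptic drive,
and their firing rate is conspicuously insensitive to background GABA-A
inhibition while remaining sensitive to excitation. The model is an
exponential integrate-and-fire (EIF) neuron extended with a saturating,
depolarization-activated inward current of the persistent-sodium class
(units pF, nS, mV, ms, pA):

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T)
              + I_NaP / (1 + exp((V_half − V)/k))
              + I_drive − g_e(t)(V − 0) − g_i(t)(V + 70) + I_stim(t)

with a spike registered at V_cut = V_T + 15 Δ_T, reset to −70 mV and a
1.5 ms refractory clamp. A plain EIF with constant drive could not
reproduce the pacemaker's inhibition insensitivity at any parameterization
we explored: with the drive calibrated to a 10–40 Hz rate, the net cycle
current is tens of pA, so the ~30 pA mean current of a realistic
background IPSC barrage always moved the rate by 30 % or more. The added
NaP-like term supplies exactly the mechanism SNr neurons are known to use:
a regenerative (negative-slope) inward current in the perithreshold
region, together with a reset at the GABA-A reversal so that the slow
segment of the interspike trajectory sits where the inhibitory driving
force is near zero. With the default parameters

| parameter | value | meaning |
|---|---|---|
| C | 150 pF | membrane capacitance |
| g_L | 5 nS | leak conductance |
| E_L | −60 mV | leak reversal |
| Δ_T, V_T | 3 mV, −50 mV | spike-initiation sharpness and soft threshold |
| reset | −70 mV | AHP trough, at E_inh |
| I_NaP, V_half, k | 250 pA, −55 mV, 4 mV | saturating subthreshold inward current |
| E_inh, E_exc | −70, 0 mV | synaptic reversals |

a 2000 Hz × 0.15 nS inhibitory barrage (the dynamic-clamp condition)
changes the 25 Hz tonic rate by about −16 %, while the matched excitatory
barrage changes it by about +97 %; the asymmetry holds across random
parameter draws in the documented ranges (the test suite checks ≥ 90 % of
50 draws). The pacemaker drive is never set by hand: `calibrate_drive`
bisects it to any target rate in [5, 60] Hz within 0.5 Hz.

Integration is fixed-step exponential Euler at dt = 0.025 ms for single
neurons (0.05 ms in the network), with the EIF exponential and the NaP
term frozen within a step; halving dt changes the spike count of a 10 s
simulation by at most one spike.

## Dynamic-clamp conductance synthesis

Synaptic conductances are built exactly as a digital dynamic clamp builds
them: Poisson event times, a unit-peak dual-exponential kernel
k(t) ∝ exp(−t/τ_d) − exp(−t/τ_r) (rise 0.5 ms, decay 5 ms for the clamp
experiments; 0.53/5.64 ms for collateral IPSC emulation), truncated where
the tail falls below 10⁻⁴ of the peak, superposed by FFT convolution and
scaled by the unitary conductance (0.15 nS). Equal rise and decay
constants raise a degenerate-kernel error rather than silently switching
to an alpha function.

## The collateral microcircuit

Neurons are placed uniformly in the 1670 × 1000 µm reference frame. Every
ordered pair connects with probability p·f(d), f a Gaussian of 600 µm
length scale (a flat kernel is available for ablation); with `p_connect`
unset, p is scaled so the mean in-degree equals 67, the center of the
50–100 range implied by the conductance budget (10 nS maximal evoked /
0.15 nS unitary). Each edge carries a delay of 1.93 ms synaptic latency
plus distance at 2 m/s. Synapses depress by resource depletion: a spike
releases U·R and the conductance of the event scales with R; U = 0.148 is
the closed-form solution of PPR(100 ms) = 0.91 at τ_rec = 200 ms. The
depression state is kept per presynaptic neuron (release is presynaptic),
not per edge.

Photostimulation injects a square current into the ChR2-expressing
fraction with a mild desensitizing onset transient (peak/steady 1.5,
τ 8 ms) and a lognormal cell-to-cell amplitude spread (cv 0.5, mean
250 pA). The heterogeneity is essential: with identical photocurrents the
whole population fires one perfectly synchronized spike and the
duration-response curve degenerates; the spread reproduces the latency and
reliability dispersion seen in cell-attached calibration recordings.
The "gabazine" flag zeroes collateral conductances while keeping
connectivity and all seeds, so control and blocked runs are exactly
paired; with the flag on, every neuron's spike train equals the uncoupled
model's train sample for sample.

### The gain experiment

For each duration (0, 4, 8, 12, 20 ms) and condition, the per-neuron
response is the spike count in a 50 ms post-onset window minus the count
expected from the same trial's pre-onset rate; at duration 0 the response
is the raw background count (a baseline-subtracted zero-stimulus response
would be noise divided by noise). Responses are normalized per neuron by
that neuron's mean inhibition-blocked response at the longest duration,
restricted to responsive neurons (reference ≥ 1 evoked spike), mirroring
the experimental restriction to cells with reliable light-evoked spiking.
A 50 ms window (not 100 ms) is used because the longer window dilutes the
evoked response with tonic spikes at these response sizes.

At the default study conditions (400 neurons, in-degree 67, 10 trials per
condition) the simulation reproduces the qualitative divisive signature:
unstimulated rates with and without collaterals differ by < 10 %, the
control/blocked response ratio declines with stimulus duration (negative
least-squares slope), the evoked-PSTH FWHM is narrower with feedback
intact, and saturating fits of response vs duration differ mainly in gain.
The magnitude of suppression is, however, shallow (ratio ~0.92–0.96 at
20 ms): the total collateral budget — ~67 inputs × 0.15 nS, scaled by
depression and a ≤ 25 mV driving force — caps the feedback current near
150–250 pA, which a minimal one-compartment pacemaker driven by a
comparable photocurrent largely shrugs off. Deep (sometimes complete)
suppression of driven spiking presumably involves factors outside this
model (dendritic placement of collateral synapses, synchronized
multi-site release, slower K⁺ dynamics after volleys).

### Paired percent inhibition

Because single-neuron percent-inhibition estimates are Poisson-noise
limited (SE ≈ 20 percentage points at 10 trials) while the within-network
shared effect is a few points, pair correlation is measured across a
*slice ensemble*: independent network realizations whose collateral
coupling is scaled by a lognormal factor (SD 0.8 in log space), emulating
slice-to-slice variability in collateral preservation and opsin
expression — the dominant source of the broad suppression spread observed
across recorded cells. Pairs of responsive neurons within each slice are
scored at 8 and 20 ms durations; the pooled Pearson r is positive
(≈ 0.05–0.2 across seeds), and vanishes when pair members are drawn from
independent realizations.

## Synthetic in vivo sessions

Units are equilibrium gamma-renewal processes (shape 4, ISI CV 0.5 —
pacemaker-like regularity; Poisson overstates the ISI variability of
tonic units) at per-unit rates drawn from 10–40 Hz, over 71 trials of 2 s
with the conditioned stimulus at 1 s. The trial's population activation
A_pre is the across-unit mean of per-unit z-scored pre-CS counts
(500 ms window; the window length is not pinned by any measurement and is
exposed as configuration). Each unit then adds Poisson transient spikes
for 200 ms at rate amplitude·(1 + cv·ε)/(1 + g·A_pre), the divisor floored
at 0.1. g = 0 yields transients independent of the population; the
reference gain g = 0.3 was calibrated once so that per-session
correlations land near the experimentally reported scale (mean r ≈ −0.13
at 12 units × 71 trials, vs −0.12 ± 0.05 reported). The generators are
pure functions of their spec including the seed.

The generator emulates stationary baselines, a single CS-locked transient,
and divisive population coupling. It does not emulate behavioral
covariates (licking, reward timing), slow drift, bursting, or pairwise
spike-count correlations beyond those induced by the shared divisor — so a
passing pipeline demonstrates correct statistics under the model, not
robustness to every feature of real recordings.

## The population-feedback pipeline

RESP_single is the unit's response-window (200 ms) rate minus its
across-trial mean; PRE_population the mean of the other units' z-scored
pre-CS rates; the session statistic is the Pearson r over all (unit,
trial) pairs, with significance from 999 within-unit trial permutations
of RESP (two-sided, add-one p). Sessions with fewer than eight units are
rejected; units with no spikes are excluded with a warning. Type-I error
is calibrated: over 1,000 null sessions the fraction with p < 0.05 falls
in [0.03, 0.07]. The pooled curve uses 20 equal-width bins on
PRE_population, keeps bins with more than five samples, and fits a
4-parameter logistic by least squares. The population score is reported
both as the pooled-pairs r and as the mean of per-session r's, which
differ when sessions differ in size.

## IPSC kinetics measurement

Onset is the first excursion above 3 baseline SDs sustained for 0.5 ms
(baseline: 5 ms pre-stimulus); the reported onset is the sample before the
crossing, which makes the noiseless latency exact. Rise time is the
interpolated 20–80 % interval. Decay is a single-exponential least-squares
fit from the peak to 90 % recovery, excluding the first five rise-times
after the peak, where the rising exponential still contaminates the decay
and otherwise biases τ upward by ~3 %; fits with R² < 0.5 are flagged and
the decay reported absent. Conductance is amplitude/(V_hold − E_Cl),
E_Cl = −70 mV. Noiseless round trips recover latency, rise and decay
within 2 % over 200 random draws. A stimulus with no detected onset
yields `None` for that stimulus — absence is a value, not an exception,
so flat traces and partial trains analyze cleanly.

## Mapping geometry

Grids are aligned into the SN frame by an orthogonal transform built from
the annotated dorsal and medial edges (flips come out of the edge basis
automatically), followed by anisotropic scaling about the grid centroid to
the 1.67:1 reference aspect, and translation of the dorso-medial corner to
the origin. The same affine is applied to somata and skeletons; weighted
centroids commute with it. Smoothed maps are sums of unit-peak Gaussians
(default σ 75 µm — the empirical response function's width is not pinned,
so it is configurable and distance statistics are also available
unsmoothed) on a 10 µm raster; isocontours come from marching squares at
0.5 (default), 0.25 or 0.2 of the maximum. The center of mass is the
response-weighted centroid of site positions; note that a "vector average
of distances to the stimulus positions" about any origin reduces
algebraically to the same point. Map correlations use only sites finite in
both maps; absent sites are never imputed as zero.

## Problem sizes and runtime

The simulations in the tests and the acceptance script are sized for a
single CPU: gain experiment at 400 neurons × 5 durations × 2 conditions ×
10 trials (the `NetworkConfig` default of 1000 neurons, a desk-scale
stand-in for the ~30,000-neuron nucleus, is used for exploratory runs);
paired-inhibition ensemble at 6 slices × 200 neurons; permutation
calibration at 1,000 sessions × 999 permutations. Connection probability
is always rescaled to preserve the biological in-degree, which is the
quantity the feedback budget depends on.

## Known limitations

* One-compartment neurons: no dendritic filtering or dendritically placed
  collateral synapses; feedback efficacy is therefore a lower bound.
* Deterministic graded release (conductance ∝ depression resource); no
  stochastic quantal failures, so tonic uIPSC *rates* are emulated only
  through the rate predictor, not the network's event stream.
* No dopamine neurons, no striatal/pallidal afferent dynamics, no
  plasticity beyond short-term depression.
* The ChR2 photocurrent is a square pulse with a simple desensitizing
  transient; channel kinetics are not modeled.
* Sessions, traces and maps are generated, not recorded; conclusions about
  pipeline correctness transfer to real data only insofar as the
  generative assumptions hold.
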