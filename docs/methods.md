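# Methods

## Scope

`tcmdbs` implements a six-population thalamocortical spiking network
(Izhikevich membranes, Tsodyks–Markram short-term plasticity),
generators for conventional and burst-patterned DBS pulse trains,
LFP/spectral analysis, Morgera's synchrony index, and an experiment
runner that compares stimulation protocols over repeated seeded runs.

## Membrane model and integration

Each neuron obeys the two-variable quadratic model
dv/dt = 0.04v² + 5v + 140 − u + I, du/dt = a(bv − u), with reset
v ← c, u ← u + d when v crosses v_p + ζ(t).  Integration is forward
Euler at dt = 0.1 ms (configurable).  The membrane white noise ξ enters
as an Euler–Maruyama voltage kick with per-step standard deviation
0.5·sqrt(dt/0.1 ms): the configured sd applies literally at the default
step, and the integrated noise power is independent of dt (measured:
off-state beta power shifts < 1% when dt is halved).  Threshold noise ζ
is a fresh draw of sd 0.1 mV at every step; it jitters the spike cutoff
comparison and is not a flow term, so it carries no dt scaling.
Voltage traces record the jittered cutoff value on spiking steps, so
integration overshoot above the cutoff never leaks into analyses.

Neurons are initialized at the stable subthreshold fixed point of their
own (b, I_bias) — the lower root of 0.04v² + (5−b)v + 140 + I = 0 —
falling back to the reset voltage where the bias exceeds rheobase.
Initializing at the reset voltage instead would start the heterogeneous
bursting cells (whose reset can sit above the unstable fixed point)
in a self-firing state and inject a large artificial onset transient.

### Heterogeneity

Per-neuron parameters are drawn with the classic network recipe:
excitatory cells c = c₀ + 15r², d = d₀(1 − 0.75r²); inhibitory cells
a = a₀ + 0.08r, b = b₀ − 0.05r, r ~ U[0,1).  The d-rule is the
multiplicative form of the familiar additive one (for regular-spiking
cells it reproduces 8 − 6r² exactly); the additive form flips d
negative for low-d categories (intrinsically bursting, relay cells),
which abolishes spike adaptation and produces runaway relay firing.
Cell categories: S = RS/IB (50/50), M = RS, D = RS/IB (70/30),
CI = FS/LTS (50/50), TCR = TC, TRN = reticular; all canonical
parameter sets, overridable per population.

## Synapses

Between spikes u decays to 0 (τ_f), x recovers to 1 (τ_d), I decays to
0 (τ_s); a presynaptic spike applies u⁺ = u⁻ + U(1−u⁻), ΔI = A·u⁺·x⁻,
x⁺ = x⁻ − u⁺x⁻, in that order (u first; the x and I jumps use the
updated u and the pre-jump x).  Three canonical classes are shipped:
facilitating (U=0.09, τ_f=670, τ_d=138), depressing (U=0.5, τ_f=17,
τ_d=671) and pseudo-linear (U=0.29, τ_f=326, τ_d=329); PSC decay
τ_s = 3 ms for glutamatergic and 11 ms for GABAergic channels.
Excitatory pyramidal→pyramidal pathways are depressing (the synaptic
suppression substrate), excitatory drive onto interneurons is
facilitating, inhibitory pathways pseudo-linear.

The network kernel updates synapses event-wise with exact inter-spike
exponentials — the same closed form as `event_driven_psc_sequence`,
which doubles as the oracle in the tests (the dt-stepped Euler variant
agrees with it to < 1% per-spike over random 130 Hz trains).  Delays
(axonal + synaptic, per projection) are realized as a circular
delay-slot buffer at dt resolution, rounded to the nearest step with a
one-step minimum.  Synapse state is per connection; postsynaptic
currents aggregate per neuron into one decay channel per distinct
(τ_s, sign) pair.

## Network reconstruction

Population sizes (100/100/100/100/100/40) are fixed by the model
definition.  Coupling weights, delays and synapse-class assignments are
a reconstruction: the values in `config.default_projections` were
chosen once so that the unstimulated ("off") network expresses the
Parkinsonian baseline this model family is defined by — elevated
beta-band LFP power (spectral peak ≈ 25 Hz, beta fraction ≈ 0.4 of
1–100 Hz power) carried by periodic population-wide synchronized
events.  The rhythm is generated by the delayed
cortico-thalamo-cortical loop (D → TCR → D, 13 ms per leg, ≈ 40 ms
round trip including synaptic integration) under inhibitory control
from TRN and CI; a control network with the same topology but permuted
projection weights shows a lower beta fraction (tested).  Projection
weights are totals per postsynaptic neuron, divided by the expected
in-degree; individual connections carry ±40% uniform dispersion, with
all-to-all connectivity (p_connect = 1, configurable).  All of this is
overridable via YAML.

## Stimulation

Pulse trains are grid-free event lists; discretization happens only at
injection, where a Dirac event of weight A becomes a one-step current
of height A/dt (its time-integral is A, i.e. an instantaneous voltage
jump of A mV).  Events live in the half-open window [onset, total).
B-DBS pack timing reads "every 37 ms" as the pause from the last pulse
of one pack to the first of the next (pack period 3/130 s + 37 ms ≈
60.1 ms ≈ 16.6 packs/s, consistent with the 16 Hz comb the pattern
imprints on the LFP); the alternative pack-onset-period reading is
available as `pause_mode="period"`.

The pulse current is delivered to a seeded random 50% of layer D.
`calibrate_amplitude` finds the smallest amplitude that 1:1-entrains
≥95% of the stimulated neurons under a 1-s 130 Hz test train
(bisection to 1%; ≈ 78 for the default network, robust to doubled
membrane noise).  The default operating amplitude is 38 — roughly half
the 1:1 value, i.e. partial entrainment.  This operating point was
fixed once during reconstruction because it is where the pattern
*identity* matters: at full entrainment every sustained pattern drives
the stimulated neurons near their depression ceiling (x recovers only
~5% during a 37 ms pause at τ_d = 671 ms) and B-DBS suppresses beta as
strongly as tonic 130 Hz, whereas at partial entrainment B-DBS
degenerates toward pack-rate (≈16 Hz) drive, leaves beta essentially
unchanged and imprints a 16.6/33 Hz comb — while its five-fold
amplitude variant recovers full-pack firing and strong suppression.

## Analysis

LFP: point-source sum, [Σ excitatory PSC onto D + Σ inhibitory PSC
onto CI] / (4πσr), σ = 0.27 S/m, r = 100 µm.  PSD: Welch, 1-s Hann
windows, 50% overlap, on the full 6-s off (0–6 s) and on (6–12 s)
segments, no transient trimming (trimming is a config option); band
power by trapezoidal integration over 13–30 Hz; attenuation =
off − on (positive = suppression).  Harmonic combs are detected as
local PSD maxima within a tolerance of k·f₀, reported with a
prominence score (peak over neighbourhood median) — on white noise,
coincidental "detections" are common but carry prominence ≈ 1,
so prominence, not bare detection, is the discriminating statistic.

Morgera synchrony: columns of the P×N activity matrix are
mean-centered, SVD'd, the squared singular values normalized to
variance fractions σᵢ (Σσᵢ = 1), C = −Σσᵢ ln σᵢ / ln N, M = 1 − C.
Silent columns (zero after centering, up to a relative tolerance) are
dropped with N adjusted and the count reported.  Two input modes
exist because the definition is ambiguous in practice: the binary
1-ms-binned spike raster with plain centering (the package default for
the metric itself), and membrane-voltage columns with per-column
variance normalization (correlation spectrum).  The experiment runner
reports both (`M_*` voltage/normalized, `M_*_spikes` binary/covariance)
and treats the voltage mode as primary: under strong entrainment the
50 perfectly phase-locked stimulated neurons form a dominant rank-1
block in the spike covariance and push covariance-M *up*, masking the
network-wide desynchronization that the variance-normalized voltage
measure (stable at M ≈ 0.56 across baseline windows) resolves.

## Experiment runner and statistics

Each repetition r of a protocol builds a fresh network realization and
noise stream from seed = base + r, runs 12 s with stimulation on at
6 s, and tabulates off/on beta power, attenuation and both M variants.
`compare_conditions` reports medians/quartiles/means and
unequal-variance (Welch) two-sample t-tests of each protocol's
attenuation against the off condition, with raw p-values and
significance marks under both common flagging schemes (0.05/0.01 and
0.01/0.001) — consumers pick their convention.  The test suite runs
the battery at 10 repetitions per protocol (a desk-scale stand-in for
the 100-repetition study design; all numbers reported by the tests are
computed at that scale).

## Determinism and performance

Everything is seeded: network realization, noise, target selection,
fixtures.  A repeated run with the same seed is bitwise identical
(the CLI determinism test compares output files byte-for-byte).  The
inner loop is a single-threaded numba kernel; a 12-s, 540-neuron,
190k-connection run takes a few seconds on one CPU core.

## Known limitations

* The coupling matrix is a tuned reconstruction, not a fitted model;
  quantitative power values are arbitrary model units and only
  orderings/ratios are meaningful.
* The Poissonian background input exists in the data model only
  (disabled flag); enabling it raises.
* At desk scale (10 repetitions) the fine ordering of the synchrony
  index among the effective high-frequency protocols (130 Hz cDBS vs
  A-DBS vs 20 Hz cDBS on-period) is not statistically resolved; only
  the attenuation orderings and the baseline-vs-stimulated synchrony
  contrasts are asserted.
* Single-compartment neurons, intracellular current injection (no
  extracellular field or charge-balanced waveforms), no basal ganglia.
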