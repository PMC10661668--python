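# Methods

## Electro-fluidic dosimetry model

The chamber model treats every electrolyte-filled rectangular microchannel
as a one-dimensional ohmic conductor: resistance *R* = *L*/(*σwh*) and,
for a channel carrying current *i*, a uniform axial field
*E* = *i*/(*σwh*). This deliberately replaces finite-element field maps
with a resistor approximation; it is exact for long straight channels away
from junctions and is the basis on which the chamber is designed as a
current divider. Networks are solved by standard nodal analysis: the
conductance matrix is assembled over all nodes, the source's negative
terminal is grounded, and the resulting linear system is solved densely
(`numpy.linalg.solve`). Kirchhoff's current law then holds at every node to
floating-point tolerance (the test suite enforces residuals below
10⁻⁹ of the input current), and all branch currents scale exactly linearly
with the source current.

Chamber wiring is **configuration, not code**: the published description of
the reference chamber gives only relative branch resistances and the
channel thickness, so the solver accepts any node/edge list. The bundled
`examples/chamber_example.yaml` is one defensible reading — a feed
resistor followed by three identical-cross-section stimulation sections in
series, with a bypass branch to the return electrode after the first and
second section. Its bypass resistances were solved analytically so that a
43.5 µA input produces 4.7 / 2.7 / 1.0 mV/mm in s1 / s2 / s3 with
σ = 1.5 S/m (physiological saline); the file is labelled an interpretation
and should be replaced with measured geometry for a real device.

Electrode-side quantities are closed-form: disk current density
*j* = *i*/(π(*d*/2)²); delivered charge *Q* = *i·t* for DC and
*Q* = *i·t*<sub>on</sub>·*n* for pulsed protocols (inter-pulse intervals
carry zero current, matching how such budgets are quoted); capacitive
window *t*<sub>cap</sub> = *C·ΔV*/*i*, reported as infinite at zero
current. The example electrode's *C* = 54.33 mF and ΔV = 0.6 V are set so
their product is 32.6 mC — the product is the only externally constrained
quantity (it fixes the 12.5 min window at 43.5 µA); the split between *C*
and ΔV is a representative choice for a conducting-hydrogel electrode.

Integral capacitance from slow cyclic voltammetry is
*C* = (∮|*i*| d*V*)/(2·ν·ΔV<sub>window</sub>) with trapezoidal integration
along the sampled loop; for an ideal rectangular voltammogram of
half-height *i*<sub>c</sub> this reduces to *i*<sub>c</sub>/ν, and the
tests require <1 % recovery at ≤1 mV sampling steps.

Voltage-excursion classification fits the trace with one line and with the
best two-segment piecewise line (exhaustive breakpoint search, each
segment ≥2 samples). The two-segment fit is adopted only when it reduces
the residual by more than 10 %; a single linear ramp with R² ≥ 0.99 is
**capacitive** (C_eff = *i*/slope), a ramp whose second-segment slope falls
below 5 % of the first is **faradaic_onset** with the breakpoint abscissa
as transition time, and a trace whose overall slope is at most 5 % of its
initial-window slope (or non-positive) is **faradaic_dominant**, with no
capacitance reported. The capacitive slope expectation *i*/*C* cannot be
used as the flatness reference without knowing *C*, so the initial-window
slope of the trace itself serves as the reference; all thresholds are
keyword-configurable because the regimes are conventionally judged by eye.

## Synthetic movie generator

The generator emulates the structure the pipeline assumes, not microscope
physics. Defaults reproduce the reference acquisition: 128×128 px, 1000
frames at 120 ms (2 min), 8-bit intensities. Thirty non-overlapping disk
somata (radius 3–5 px, ≥2 px clearance, rejection-sampled) receive
baselines uniform in 80–140 counts over a 20-count background; the nuclear
channel renders the same disks statically at 180 counts. Activity mixes a
shared network-event Poisson process (default 3 events/min, per-neuron
participation 0.8) with private Poisson spikes (2/min); each spike adds an
instantaneous-rise, single-exponential transient (amplitude 0.3·F₀,
τ = 0.4 s — a fast-indicator-like kernel; the default amplitude over
σ = 5 counts of additive Gaussian noise on ~100-count baselines gives
per-event SNR ≥ 5). Bleaching is a multiplicative exponential with a
1200 s time constant (ten movie lengths — a mild, realistic drift); shot
noise is available as an option. Rendering clips to [0, 255] and warns if
more than 1 % of in-cell pixel-frames clip.

What the generator does **not** model: dendrites and neuropil
contamination, overlapping somata, motion, optical PSF, indicator
nonlinearity and saturation. Passing recovery tests on these movies
therefore demonstrates the pipeline's correctness under its own
assumptions, not robustness to those real-data effects.

Determinism: a single integer seed is split (`numpy.random.SeedSequence`)
into independent streams for placement, spiking and noise, so movies are
bit-reproducible.

## Cell detection

Chain, in order, on the temporal mean of the nuclear channel: median blur
(default 3 px) → grey-scale opening with a 32 px footprint, taken as the
background and subtracted (clipped at zero — 8-bit background removal
cannot go negative) → grey-scale opening with a 2 px footprint → binary
threshold at 100 counts → connected components (8-connectivity) → discard
components with area ≤ 20 px (strictly; a 20 px component is rejected, a
21 px one kept) → relabel 1..K in raster order of each component's first
pixel. Structuring elements are square by default ("kernel size k" read as
a k×k footprint, the common computer-vision default) with a disk option;
blur size, connectivity and threshold are all parameters because the
reference description leaves them partly unstated. `scipy.ndimage`
provides the morphology; the tests cross-check it against explicit
sliding-window median/min/max oracles.

## Trace analysis

Raw trace: spatial mean over the ROI per frame. Trend: centered rolling
median, window 20 frames, window shrinking at the edges (centered to avoid
phase lag; pandas' rolling median with `min_periods=1`). ΔF/F₀ =
(F − trend)/mean(trend): normalizing by the mean of the trend (rather than
per-frame) makes the trace dimensionless and invariant to rescaling the
raw fluorescence. Spikes: threshold θ = mean + k·SD of the full processed
trace (k = 3; SD over the full trace, events included, matching the stated
rule); calls are the supra-threshold local maxima
(`scipy.signal.find_peaks`), with peaks closer than 2 frames merged
(taller wins). Counting peaks rather than threshold crossings was chosen
because it keeps the call count non-increasing in k — raising the
threshold can split one supra-threshold run into several runs but never
creates a new local maximum — and reports the same peak frames in the
common case of well-separated transients. Rates are counts over the
session length in minutes, optionally divided by the baseline-session mean
rate of the same culture (so baseline group means are 1 by construction).

## Group statistics

Neuron-level: unpaired two-sample t-test, Welch by default (pooled
available), two-sided, with a t-distribution CI; the degenerate case of
zero variance in both groups with equal means returns t = 0, p = 1. The
statistic is implemented directly and verified against
`scipy.stats.ttest_ind` to 10⁻¹⁰, and its type-I error is calibrated by
simulation (10⁴ null replicates, 0.05 ± 0.01 at α = 0.05).

Culture-level: because neurons within a culture are correlated, the
grouping-aware check resamples **cultures** with replacement within each
condition (2000 replicates by default), recomputing the neuron-weighted
mean difference; the percentile interval is the CI and the bootstrap
p-value is twice the smaller tail fraction around zero. This replaces a
linear-mixed-model fit: the contract is the clustering-aware conclusion,
and the bootstrap delivers it without a model choice. At least two
cultures per condition are required.

## Problem sizes and numerical notes

- The test suite's recovery checks use 10 seeded reference-condition
  movies for segmentation and 3 for spike F1; `scripts/acceptance.py` uses
  4 and 3 (each movie is an independent replicate; the scores are means
  across movies). The type-I calibration uses 10⁴ replicates in both.
- All randomness flows from explicit integer seeds; derived seeds are
  reduced mod 2³¹.
- The nodal solver uses a dense solve — chamber networks have a handful of
  nodes; singular systems and disconnected source terminals raise typed
  errors rather than propagating NaNs.
- CV integration error is second-order in the potential step
  (trapezoidal); the ideal-capacitor round-trip bound (<1 %) holds for
  steps up to 1 mV over windows ≥0.5 V.
- Degenerate inputs: zero input current yields all-zero fields; a
  zero-variance ΔF/F₀ trace yields no spike calls; empty ROIs, empty
  stacks and non-monotonic excursion time axes raise typed errors.

## Known limitations

The resistor model ignores junction effects, electrode polarization
overpotential and the tissue's own conductivity contrast; the excursion
classifier assumes a single transition; the generator omits the real-data
nuisances listed above; and the cluster bootstrap assumes cultures are
exchangeable within condition (few-culture datasets give coarse,
conservative intervals).
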