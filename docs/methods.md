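# Methods

This note documents the models implemented in `ca1mf`, the calibration
choices behind the shipped defaults, and the limits of what the validation
suite demonstrates.

## Single-cell model

Both cell types (CA1 pyramidal cells, Pyr; fast-spiking interneurons, FS)
are EGLIF point neurons: a leaky integrate-and-fire membrane plus a slow
adaptation current `I_adap` (driven by `k_adap (V - E_rev)`, decaying at
`k_2`) and a fast post-spike depolarizing current `I_dep` (reset to `A_1`
at each spike, decaying at `k_1`). The leak is attractive,
`-(C_m/tau_m)(V - E_rev)`; a `printed_leak_sign` switch exposes the
repulsive variant for inspection only (it is dynamically unstable).

The published parameter set is unusual in magnitude (`C_m ~ 2.9 nF`,
`tau_m ~ 11 s` for Pyr), giving a leak conductance of only ~0.26 nS. We
use the values exactly as published. Consequences run through everything
below: the membrane is an almost pure integrator, the effective time
constant is set nearly entirely by synaptic conductance, and any
uncompensated excitation pulls the mean voltage far above threshold.

Three spike-mechanism constants are not part of the published set and are
calibration parameters of this package:

| parameter | Pyr | FS | rationale |
|---|---|---|---|
| `V_th` | -55 mV | -45 mV | see below |
| `V_r`  | = `E_rev` | = `E_rev` | reset to rest; makes the zero-input rest state exact |
| `t_ref` | 2 ms | 2 ms | conventional absolute refractory period |

The thresholds were calibrated once at network level: with both
populations driven by the external CA3 input at 2-8 Hz, the circuit must
have an active, balanced operating point (Pyr ~1-3 Hz, FS ~5-20 Hz, the
ranges observed in hippocampus). More excitable FS settings (e.g. FS
threshold a few mV above rest) let feedback inhibition silence the
pyramidal population completely, which contradicts the phenomena the
model exists to reproduce. The calibration also keeps the moment-closure
correction (below) small relative to the rates, i.e. the mean-field
expansion inside its validity domain.

Synapses are conductance-based alpha kernels
`Q (t/tau_syn) exp(1 - t/tau_syn)` with `Q_Pyr = 1.5 nS`, `Q_FS = 8 nS`,
`tau_syn = 5 ms`, `E_e = 0`, `E_i = -80 mV`. The kernel is integrated as
its exact two-variable linear realization with exponential propagators, so
the peak conductance equals `Q` independent of `dt`. `V` is advanced by
explicit Euler (`dt = 0.1 ms` default); `I_dep` and the decay of `I_adap`
use exact exponential propagators (the post-spike `I_dep` trace therefore
matches its closed form to machine precision). Events delivered in a step
take effect at the step's start; network spikes detected at the end of a
step reach their targets in the following step (zero axonal delay at `dt`
resolution).

## Microcircuit

5,000 Pyr + 500 FS with independent Bernoulli connectivity
(`p(Pyr->Pyr) = 0.01`, `p(FS->Pyr) = 0.3`, `p(Pyr->FS) = 0.2`,
`p(FS->FS) = 0.3`) and 5,000 external Poisson sources (CA3) contacting Pyr
with p = 0.15 and FS with p = 0.3. The external drive is realized exactly:
the merged event stream of rate `N_ext nu(t)` is tagged with uniform
source identities (marking theorem) and fanned out along each source's
realized target list; a `merged` per-target approximation (no
shared-source correlations) is available.

Validation experiments run a one-fifth circuit (1,000 Pyr + 100 FS,
`N_ext = 1,000`), which preserves the excitation/inhibition balance
because all convergences `K = pN` scale together. Stationary rates
discard the first 1,000 ms (slow intrinsic currents) and average over the
following >= 5 s.

## Transfer function

For each cell type the stationary output rate under Poisson bombardment
is written as `F = 1/(2 tau_V) erfc((V_eff - mu_V)/(sqrt 2 sigma_V))`,
with subthreshold moments computed in closed form from shot-noise theory
for the alpha-conductance kernels. Conventions:

* the kernel time integral contributes a factor `e`
  (`int Q (t/tau) e^(1-t/tau) dt = e Q tau`), applied uniformly:
  `mu_Gj = e Q_j tau_j nu_j K_j`, and the per-type voltage jumps enter the
  variance and correlation-time sums as `e U_j`;
* `tau_V^N = tau_V g_L / C_m`, and the effective threshold is a linear
  expansion in `(mu_V, sigma_V, tau_V^N)` (normalizations
  `mu_V: -60 +- 10 mV`, `sigma_V: 4 +- 6 mV`, `tau_V^N: 0.5 +- 1`) plus a
  `ln(mu_G/g_L)` term; an optional quadratic cross-term expansion exists
  behind a flag (default off — it overfits 24-point sample sets);
* excitatory sources with identical `(Q, tau, E)` pool exactly through
  `K nu`, which is how recurrent and external excitation combine.

The closed-form moments were verified against threshold-free Monte-Carlo
simulation (within 2 mV / 20% over a 3x3 grid in the diffusion domain;
with sparse large-quantum input, e.g. 8 nS FS quanta at ~1 Hz, the
linearization biases `mu_V` by several mV — a known limit of shot-noise
moment expansions).

**Sampling.** The erfc form saturates at `1/tau_V ~ mu_G/C_m`. With these
high-capacitance cells a neuron with weak inhibition is mean-driven and
fires far above that bound, so rectangular `(nu_e, nu_i)` grids place many
samples outside the formalism's domain. The numerical transfer function is
therefore sampled along balanced rays `nu_i = r nu_e` with ratios
bracketing the circuit's operating ratio (Pyr: r in 1.5-5, FS: 2-7; base
rates log-spaced 0.5-10 / 0.5-8 Hz; 40 s per point, all points integrated
concurrently as one neuron bank). Fitting is two-stage: exact inversion of
the erfc relation maps every invertible sample to a target `V_eff`,
followed by ordinary least squares in the expansion's regressors, then a
rate-space nonlinear refinement (default on). Where no samples are
invertible (the saturated, disinhibited regime) the refinement starts from
a bare threshold at `V_th`.

## Mean-field model

Second-order moment closure over the two populations: rates `nu_mu` relax
toward `F_mu` with `T = 5 ms`, carrying a curvature correction
`1/2 c_lam_eta d2F/dnu dnu`, while the rate covariance `c` obeys the
master-equation form with the finite-size source
`delta_le F_l (1/T - F_e)/N_l`. Derivatives of `F` are central finite
differences (step `max(0.1 Hz, 0.01 nu)`, one-sided at the `nu = 0`
boundary). Integration is Heun at `dt = 0.1 ms` with clip-at-zero (events
counted); stationary states come from `hybr` root finding with a damped
fixed-point fallback, and the full second-order fixed point solves the
5-dimensional `(nu, c)` system.

**First-order comparisons.** Validation against the spiking network quotes
the first-order rate prediction (`c -> 0`). Measured across seeds, the
first-order rates agree with the network within 4-19% at all drives and
all plasticity weights. The second-order curvature term, in contrast,
systematically *adds* ~0.1-0.2 Hz to the pyramidal rate: the finite-size
source assumes Poissonian population fluctuations, while the
drive-dominated FS population spikes more regularly than Poisson, so the
model overestimates the FS rate fluctuations whose convex transfer onto
the pyramidal erfc tail produces the excess. At pyramidal rates of a few
Hz this is a 10-20% overestimate; at the near-silent rates reached when
the external convergence is halved it is a multiple of the rate itself.
The second-order pathway remains the full shipped model and is reported
alongside in every comparison object.

**Adaptation is quasi-static.** The intrinsic currents do not appear in
the mean-field state; their stationary effect is inside the fitted
transfer function. Under slow time-varying drives this is visible: for a
Gaussian drive pulse of width `sigma_t = 100 ms` the network's pyramidal
response centroid leads the mean-field's by ~20 ms (the network adapts
while the pulse is still rising), the lead scaling roughly linearly with
`sigma_t` (10 ms at 50 ms, ~3 ms at 25 ms) and independent of amplitude.
Pulse timing is measured as the rate-weighted centroid of the
above-baseline response in a +-3 sigma window; an argmax on the flat top
of a slow pulse is dominated by counting noise.

**Oscillatory drives.** Sinusoidal drives at theta (6 Hz) and gamma
(50 Hz) produce population rates whose spectra peak at the drive
frequency. The naive expectation that the `T = 5 ms` relaxation low-passes
gamma more than theta does not hold here: the Pyr-FS loop amplifies input
near `1/(2 pi T) ~ 30 Hz`, so the gamma response is resonantly enhanced.

**Plasticity.** `W_e` scales the external CA3->Pyr convergence
(`K_ext->Pyr * W_e/100`); the network realizes the same change by
rebuilding the graph with `p_ext->Pyr` scaled. Stationary pyramidal rates
rise strictly with `W_e` in both descriptions over 50-150%.

## Macroscale slice

A 1.5 x 1.5 mm patch of the pyramidal layer is tiled into 15 x 15
compartments of 100 um (~200 neurons each), one first-order mean-field
unit per compartment (inter-compartment covariances are not modeled, so
the within-compartment curvature term is dropped for consistency).
Excitatory Pyr->Pyr coupling between compartments comes from smooth
geometric neurite densities: the axonal cloud is a two-component
elliptical Gaussian mixture displaced downstream along the
CA3->subiculum axis (semi-axes 400x150 and 250x150 um, offsets +150 and
+400 um; treated as 2-sigma extents), and the basal-dendrite cone enters
as a flat 150 um footprint folded into the kernel width — the axonal
geometry is the binding constraint. These dimensions are package defaults
chosen to span a few compartments; they are fully configurable.

The convergence matrix is normalized so the total recurrent excitatory
convergence received at the grid center equals `p(Pyr->Pyr) * N_slice`
= 0.01 x 45,000 = 450. Anchoring instead to the 5,000-neuron
microcircuit's K = 50 leaves the disinhibited recurrent loop gain below
one (the erfc saturation bound `~mu_G/C_m` caps the compartment gain) and
no traveling front can exist; the slice-wide anchor restores gain > 1
while using only the published pairwise probability.

Propagation experiments silence inhibition (the regime in which CA1
slices show CA3->subiculum directionality) and use transfer functions
fitted along the `nu_i = 0` ray, since the balanced-ray fit never
approaches zero inhibition. The baseline drive is zero — the quiescent
state is then an exact fixed point — and a 40 Hz, 15 ms external stimulus
to a single CA3-side compartment ignites a front. With the default
anisotropic geometry the front sweeps transversally (latency monotone
along the row, Spearman rho ~ 1) with lateral recruitment completing only
after the front nears the subiculum edge; the isotropic control
(centered circular cloud, center stimulus) yields an anisotropy index of
exactly 1 by symmetry. The anisotropy index is the ratio of the
latency-distance slope along the longitudinal axis to that along the
transversal axis through the stimulated compartment.

In this saturated regime the erfc transfer function underestimates true
EGLIF firing (measured single-cell rates exceed the `1/tau_V` bound
severalfold), so compartment rates are meaningful as activation order and
relative amplitude, not as absolute firing rates.

## What the validation does and does not show

The spiking network is itself synthetic — the oracle hierarchy is
single-cell simulation -> fitted transfer function -> mean-field ->
compartment grid, each layer checked against the one below at desk scale
(one-fifth network, 24-point transfer-function samples, 15 x 15 grid).
Passing tests show internal consistency of the multiscale stack under the
published cell/synapse/connectivity constants, not agreement with
biological recordings. Known gaps: no synaptic delays, no plasticity
inside the spiking network, Poisson-input assumptions in the transfer
function (sub-Poisson recurrent spiking is exactly what the second-order
closure misestimates), quasi-static adaptation, and a smooth-density
stand-in for the published geometric probability volumes whose exact
dimensions are not public.

## Numerical summary of shipped tolerances

* integrator: `dt = 0.1 ms`; halving `dt` changes fixed-input spike counts
  by < 2%;
* transfer-function fit: rate RMSE < 15% of the sample maximum per cell
  type (measured ~1-3% for Pyr, ~3-10% for FS);
* mean-field vs network: stationary rates within 20% (constant drives
  2-8 Hz), plasticity sweep within 25% per point, pulse-average rates
  within 20%, FS pulse timing within 10 ms (Pyr timing carries the ~20 ms
  adaptation lead discussed above);
* slice: latency monotone (rho > 0.95), anisotropy index > 1 (default
  geometry ~11), isotropic control 1.00 +- 0.10.
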