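# Methods

## Model

A single neuron receives spikes from `n` independent Poisson afferents
with rates `r_i`. Each spike train is low-pass filtered by the
double-exponential PSP kernel

    eps(t) = eps0 / (tau_m - tau_s) * [exp(-t/tau_m) - exp(-t/tau_s)],  t >= 0,

whose time-integral is `eps0` and whose squared integral defines
`c_eps = 2 (tau_m + tau_s) / eps0^2`. The filtered trains are the
unweighted synaptic potentials (USPs) `x_i`; for constant rates they are
stationary with mean `eps0 r_i` and variance `r_i / c_eps`. The somatic
potential above rest is `V = sum_i w_s,i x_i` and output spikes are
drawn per time bin `dt` as Bernoulli with parameter `phi(V) dt` — a
point-process GLM. The default transfer is sigmoidal,
`phi(V) = phi_max / (1 + exp(-beta (V - theta)))` with `phi_max` =
100 Hz, `beta` = 0.3/mV, `theta` = 10 mV above rest; a rectified
quadratic `phi(V) = (V - theta)^2 / 4` is provided as the analytically
transparent special case with `(phi')^2 / phi = 1`.

**Units.** Internally mV and seconds; rates in Hz. The default kernel
integral is 1 mV·s with `tau_m` = 10 ms and `tau_s` = 3 ms, giving a
USP kernel peak near 60 mV per unit weight. With weights of order
`1/n` this puts single-input PSPs at a few hundred microvolts and the
mean potential within roughly ±30 mV of rest — the operating range of
the sigmoid. This scale is the one under which all quoted protocol
constants (learning rates, `cw` = 0.05, the 0.8 Hz convergence
criterion) are mutually consistent; configs state time constants in ms
and convert at the boundary. The kernel formulas themselves are
unit-agnostic.

## Fisher geometry

Supervised learning minimizes the per-bin Kullback–Leibler divergence
between a teacher's Bernoulli spike distribution and the student's. The
Euclidean gradient gives the classical error-correcting rule
`eta [Y* - phi] (phi'/phi) x`. The natural gradient premultiplies this
by the inverse Fisher information matrix of the neuron's input–output
distribution, `G(w) = E[dt (phi')^2/phi x x^T]` over the stationary USP
density.

For many afferents of comparable influence the membrane potential is
approximately Gaussian with mean `mu_v = eps0 sum w_i r_i` and variance
`sigma_v^2 = sum w_i^2 r_i / c_eps`, and G collapses to the
rank-structured closed form

    G = c1 (eps0^2 r r^T + Sigma) + c2 eps0 [S w r^T + r (S w)^T] + c3 (S w)(S w)^T

with `Sigma = S = diag(r_i / c_eps)` the USP covariance. The scalars
c1–c3 derive from three generalized voltage moments I1–I3: Gaussian
expectations of `(phi')^2/phi * {1, u, u^2}`, evaluated by
Gauss–Hermite quadrature (200 nodes; a doubling check guards
convergence; `scipy.special.roots_hermite` supplies stable nodes).
Two Sherman–Morrison steps then give the exact inverse

    G^-1 = (1/c1) [ Sigma^-1 + (g1 rt + g2 w) rt^T + (g3 rt + g4 w) w^T ],

where `rt = eps0 Sigma^-1 r = c_eps eps0 1` is constant. A rank-2
Woodbury path is kept as a cross-check. Correctness is established
against two oracles: dense numeric inversion (relative Frobenius error
~1e-14 over random configurations) and a Monte-Carlo estimate of G from
sampled stationary USP vectors (1.2% at 10^6 samples for n = 100).

The closed form inherits the Gaussian-voltage assumption: for very few
afferents with large individual influence (voltage excursions spanning
strongly curved stretches of the transfer function) it deviates from
the Monte-Carlo Fisher by tens of percent. This is a property of the
approximation, not of the implementation, and the tests probe it only
inside its stated domain.

## The learning rules

Multiplying the Euclidean gradient by the closed-form inverse yields
the natural-gradient rule in an arbitrary component-wise parametrization
`w_s = f(w)`:

    dw/dt = eta gamma_s [Y* - phi] (phi'/phi) (1/f'(w))
            [ c_eps x / r  -  gamma_u 1  +  gamma_w f(w) ],

with `gamma_s = 1/c1` (output-dependent global scaling),
`gamma_u = -c_eps eps0 (g1 c_eps eps0 sum x_i + g3 V)` (uniform
heterosynaptic), and `gamma_w = g2 c_eps eps0 sum x_i + g4 V`
(weight-proportional heterosynaptic). The homosynaptic term is
normalized by the USP variance (`c_eps / r_i`), so unreliable inputs
learn more slowly. The rule's somatic image is invariant under any
smooth component-wise coordinate change (verified to 1e-10); the
Euclidean rule instead picks up exactly `f'(w)^2`.

The approximated rule replaces the heterosynaptic factors with
synapse-local surrogates `gamma_u -> cu c_eps` (cu = 0.95) and
`gamma_w -> cw V` (cw = 0.05, close to the sampled mean of g4);
`gamma_s` stays exact. The quadratic-transfer limit has `gamma_s = 1`,
`gamma_w = 0` and `gamma_u = c_eps^2 eps0^2 sum x_i / (q + 1)` with
`q = c_eps eps0^2 sum r_i`.

**Discretization.** Forward Euler with `dt` = 0.5 ms. Teacher spikes
enter as unit impulses (per-bin error `y - phi dt`); USP filtering uses
exact per-bin exponential state updates, so traces equal the
convolution at grid points up to spike binning. At most one spike per
bin per train (Bernoulli thinning of the Poisson process).

**Silent afferents.** A zero-rate afferent would make the USP
covariance singular; its homosynaptic term is set to zero (the limit of
an infinitesimal rate) while both heterosynaptic terms continue to act
on it. Its rate contributes nothing to the coefficient sums.

**Tonic inhibition** is a constant negative shift of the operating
voltage, implemented as a shifted transfer function so that the Fisher
moments see the weight-driven potential and the rate is read out at the
shifted value.

**Coefficient refresh.** gamma_u and gamma_w are re-evaluated from the
current USP vector every bin; the underlying g-coefficients depend on
the weights only and are refreshed every bin by default. Long runs may
refresh them every few bins (the acceptance runs use 10 bins = 5 ms;
per-bin relative weight drift is ~1e-5, so the coefficients are
unchanged to float precision).

**Execution.** The online learner is vectorized over weight replicas
(trials or grid cells). A numba-compiled kernel fuses spike
generation, USP filtering, teacher sampling and the update for the
common case (sigmoid transfer, linear parametrization); the plain
numpy loop is the reference implementation and the two are pinned
against each other in tests. Spike thresholding uses float32 uniforms
in both paths; all state is float64.

## Simulation protocols

* **Teacher–student task.** n = 100 afferents, half at 10 Hz, half at
  50 Hz; realizable teacher; initial and target weights uniform on
  (-1/n, 1/n); tuned learning rates per rule and rate pattern
  (natural 6e-4, Euclidean 4.5e-7 for the 10/50 pattern; a table covers
  the other patterns). The cost is the analytic per-bin Bernoulli KL
  divergence averaged over a per-trial test set of 50 stationary USP
  vectors (each the endpoint of a 250 ms input train); the 5e-5
  threshold is interpreted on this per-bin scale. Trials are batched;
  each has independent inputs, teacher spikes, and weights derived from
  named substreams of one master seed, so rule comparisons share their
  task instances. The default duration (4000 s simulated) is where the
  natural rule's RMSE curve flattens below the 0.8 Hz criterion; the
  trial count default is scaled down to 20–50 from the reference 1000
  for desk runs (trial-mean curves are smooth at this size).
* **Democratic plasticity.** One excitatory synapse, 5 Hz input, 20 Hz
  Poisson teacher, 5 s of learning, initial somatic amplitude 0.05;
  dendritic coordinates with attenuation alpha(d), initial dendritic
  weight scaled by 1/alpha(d). Both a linear inverse-distance and an
  exponential attenuation profile are available. All distances share
  one spike/teacher realization, so the somatic-amplitude change is
  identical across distances up to float noise and the dendritic change
  scales exactly as 1/alpha(d).
* **Variance scaling.** One synapse, 80 Hz teacher, 5 s; USP variance
  varied through the synaptic time constant (1–20 ms at 10 Hz) or the
  input rate (10–50 Hz at 20 ms), with the kernel scale renormalized
  proportionally to the rate so the mean USP stays fixed at 10 mV.
  Learning rate as in the main task (not printed for this protocol).
* **Homo-/heterosynaptic grid.** 10 synapses, 5 stimulated at 5 Hz,
  teacher 20 Hz, 60 s, eta = 0.01, tonic shift -5 mV; equal initial
  weights within each group, swept over [1/n, 5/n]^2. Sign regimes:
  stimulated-LTP/unstimulated-LTD (O1), the reverse (O2), and joint
  depression (S) in the large-weight corner.
* **Coefficient sampling.** g1–g4 over rates 5–55 Hz (n = 100) and
  n = 10–200 (20 Hz), 20 weight draws from U(-5/n, 5/n) each; gamma_u
  against its surrogate `s = c_eps sum x / sum r`, gamma_w against
  `g4 V` and `cw V` with 20 stationary USP draws per condition.
* **Update angles.** For five rate patterns, 100 (scaled down: 20)
  weight draws from U(-5/n, 5/n) and as many 1 s spike-train draws,
  the three rules' updates are accumulated with frozen weights and the
  angles between them measured in the Euclidean metric and in the
  Fisher metric G(w) of the initial weights.

## What the generator does and does not emulate

Inputs are homogeneous Poisson trains; there is no refractoriness, no
conductance-based synapses, no rate modulation, no cross-afferent
correlation, and dendrites enter only through a static per-synapse
attenuation factor. A green suite therefore establishes the internal
consistency of the theory (closed forms vs oracles, invariance,
convergence ordering) under its own stated assumptions — not
performance on correlated or nonstationary biological input.

## Numerical choices and edge cases

* Gauss–Hermite with 200 nodes; degenerate `sigma_v^2 = 0` falls back
  to the integrand at the mean; the quadratic transfer's rectification
  contributes zero to the moments where `phi = 0`.
* `phi = 0` inside ratio terms raises unless an explicit floor is
  configured; experiments keep voltages inside the transfer support.
* Vanishing k1/k2 denominators raise (degenerate configurations).
* Non-finite weights flag a trial as diverged; diverged trials are
  reported, not silently dropped.
* Learning-curve DKL thresholds: the Euclidean rule can cross *loose*
  (high) DKL levels earlier than the natural rule because its
  high-eigenvalue modes decay quickly; the convergence-ordering claims
  are therefore stated at thresholds in the convergence regime
  (<= 1e-4 per bin, including the reference 5e-5).

## Known limitations

* The closed-form Fisher (and hence gamma_u/gamma_w) is exact only in
  the large-n Gaussian-voltage regime; single-synapse protocols use the
  same formulas, as the reference protocols do, but their coefficients
  there are an extrapolation.
* Time-to-threshold resolution equals the snapshot interval of the
  learning curve.
* The compiled engine covers sigmoid transfer and linear
  parametrizations; other combinations run on the (slower) reference
  path.
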