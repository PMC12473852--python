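# Methods

`phytomc` implements a molecular-communication (MC) model of inter-plant
stress signalling: a stressed transmitter plant encodes its stress type in a
characteristic biogenic volatile organic compound (BVOC), the compound
drifts and diffuses through the air, and a receiver plant detects and
demodulates it by thresholding the mass its leaves absorb. This note
records the model, its assumptions, the parameter choices, and what the
validation suite does and does not establish.

## Model chain

### Stress alphabet

Each stress type maps one-to-one onto a single compound (`MoleculeSpec`):
methyl jasmonate (b1, pest stress) and ethanol (b2, heat stress) in the
default two-molecule alphabet, with diffusion coefficients D_b1 = 0.007 and
D_b2 = 0.009 m²/s. The model assumes no cross-interaction between
compounds and no co-release of multiple compounds per stress.

### Transmitter

Synthesis is driven by a gene-regulatory ODE with additive regulation and
no autoregulation:

    ξ(t) = dG_x/dt = η_x1 σ(a_x0 + Σ_y a_xy G_y) − η_x2 G_x,

with σ the logistic sigmoid. The compound partitions into aqueous and
lipid storage pools (fraction η vs 1−η) that drain with rates u_a, u_l into
a gas-phase pool venting to the atmosphere at rate u_g, giving the release
rate J(t) = u_g Q_g(t). No numeric values exist for these constants in the
source setting; the defaults η = 0.5, u_a = u_l = 0.1 s⁻¹, u_g = 0.05 s⁻¹,
a_x0 = 0, η_x1 = 1 mg/s, η_x2 = 0.1 s⁻¹ give order-one dynamics on the
seconds timescale of the channel and are overridable in every config.

Numerics: the nonlinear gene ODE is advanced by classical RK4 with internal
steps capped at 0.1/max(η_x2); the linear pool system is advanced by the
*exact* matrix-exponential step of the augmented system (pools + cumulative
emitted mass) under piecewise-constant ξ, so the mass-balance audit
(produced = pools + emitted) holds to machine precision by construction and
is asserted at < 1e−6 relative in tests. Units: mg, s, m throughout.

The "arrived mass" convolution is implemented as the expected cumulative
arrival ∫₀ᵗ J(δ) F_hit(t−δ) dδ; an impulsive release of mass M at t = 0
(the initial condition under which the channel density is derived) then
gives exactly M·F_hit(t). Impulse mode is the default for all experiments.
ξ is treated as a mass rate (mg/s) via η_x1; the gene-expression and
mass-rate readings of ξ are not distinguished by the model.

### Channel

The receiver is a perfectly absorbing sphere of radius R = 0.15 m; the
transmitter is a point source a distance d upwind. The first-hitting-time
density is

    f(t) = (R d/(R+d)) (4πD t³)^(−1/2) exp(−(d−vt)²/(4Dt)),

the no-drift absorbing-sphere solution with the drift inserted in the
exponent. Its closed-form peak time is implemented in the rationalized
form t_peak = 2d²/(6D + √(36D² + 4v²d²)), identical algebraically to the
quadratic-root expression but stable as v → 0 (limit d²/6D, no branch).
F_hit(ω) = ∫₀^ω f dt is evaluated by adaptive quadrature (absolute
tolerance 1e−10, lower cutoff 1e−12 s for the removable t = 0 singularity,
break points at the density peak). Because the cumulative curve is built
from per-segment adaptive quadrature it is grid-independent: refining the
output grid does not move the values, so the low-wind discretisation
artifacts that step-sensitive integration can produce are absent by
construction. d is always the point-to-surface distance, so the still-air
all-time capture probability is R/(R+d). Negative v (upwind receiver) is
rejected, not extrapolated.

**Known limitation (quantified, not repaired):** for v > 0 the
drift-in-exponent form still integrates to the no-drift total R/(R+d).
The Brownian-particle simulator shows that at Péclet number vR/D ≈ 56
(v = 3 m/s, d = 1 m) the true capture probability by 2 s is ≈ 0.90, versus
0.13 from the closed form: the heuristic badly underestimates downwind
capture at high Péclet. The package implements the closed form as the
model prescribes and ships the particle oracle to measure the gap; tests
assert the sign of the discrepancy only.

Leaf-surface concentration: C_leaf = 3 M F_hit/(4πR³φ), with φ the ratio of
actual leaf volume to sphere volume.

### Receiver

Uptake into leaf tissue is first-order with rate
β = A_L ρ_L g/(K_L m_L); C_abs(t) = (K_L C_leaf/ρ_L)(1 − e^(−βt)), and the
absorbed mass over a stomatal window τ uses the closed-form integral
I(τ) = τ − (1 − e^(−βτ))/β:

    M_abs = M F_hit · 3 m_L K_L/(4πR³ φ ρ_L) · I(τ).

Leaf constants: A_L = 0.009 m², g = 86.4 m/day, ρ_L = 1000 kg/m³ (the
tabulated "kg/m²" is read as a density; water-like tissue), m_L = 0.05 kg,
K_L = 20. Two conductance conventions are provided as an explicit switch:

* `si` (default): g = 86.4 m/day = 1.0e−3 m/s, β = 0.009 s⁻¹,
  I(2 s) = 0.0179 s;
* `as_printed`: the numeral 86.4 used with seconds, β = 777.6 s⁻¹,
  I(2 s) = 1.9987 s.

The magnitudes of the published absorption and detection-error curves
(e.g. a 2.1e−4 mg threshold against M = 1.6e−3 mg emissions) are reachable
only in `as_printed` mode, so the absorption/detection experiments and the
reproduction script use it; the SI mode is kept for dimensionally
consistent uptake work. Note the τ-integral formally yields mg·s; the
model's convention treats the result as a mass in mg and compares it to mg
thresholds, and the package follows that convention.

### Detection

Slots have duration T_s; the detection window of slot m is centred on
t_peak with width T_s (lower edge clamped at 0), and q_m is the hit
probability captured by window m. Emission for slot λ occurs at
(λ−1)T_s; causality (λ ≤ k) is enforced. Slot indices are 1-based.

The slot-k observation for a molecule is signal + ISI + noise with Gaussian
moments

    μ_k = M q₁ + Σ_{λ<k} p M q_{k+1−λ} + μ_n,
    σ_k² = M q₁(1−q₁) + Σ p M q(1−q) + σ_n²,

absorption scaling the mean linearly and the variance quadratically. An
interfering (non-transmitted) molecule carries ISI + noise only. The
detection error rate is

    DER = 1 − Q((θ_i − μ_abs,i)/σ_abs,i) · Π_{j≠i} Q((μ̂_abs,j − θ_j)/σ̂_abs,j),

with Q the standard normal right tail computed via erfc; zero-variance
statistics degrade to step functions rather than divisions. Demodulation
declares stress s_i iff exactly molecule b_i meets or exceeds its threshold
(≥, as in the decision rule); anything else is the `error` symbol.

Three modelling conventions deserve emphasis:

* **Counts vs mass.** The binomial moments require a molecule count; the
  source model uses mg masses as binomial sizes. The package converts
  masses and thresholds with a configurable molecules-per-mg constant
  (default 1e6) and evaluates the Gaussian model on the count scale. The
  DER genuinely depends on this granularity (it sets the relative
  fluctuation scale); it is a study condition, fixed once.
* **Noise/SNR mapping.** SNR is defined only as signal power over noise
  power; the package closes the two-unknown noise model with
  σ_n = M q₁/√SNR and μ_n = σ_n. The trailing "+μ" term in the published
  mean expression is read as the noise mean μ_n, consistent with the
  signal decomposition.
* **ISI coin.** The closed form folds the per-slot transmit probability p
  (default 0.5, unspecified upstream) into the binomial moments, omitting
  the mixture term p(1−p)(Mq)². The symbol-trial oracle samples the real
  Bernoulli×binomial mixture; under the study channels the post-window
  tails q_{m≥2} are ≈ 0, so the omission is numerically irrelevant there.
  A Gaussian-validity warning fires when M q₁ < 100.

## Monte Carlo oracles

*Particles.* N independent particles start at the source and take Gaussian
increments with per-axis variance 2D dt plus drift v·dt; absorption is
checked at end-of-step (no Brownian-bridge correction), so dt must be small
near the absorber. Fixed-dt mode (default dt = 1e−4·min(t_peak, R²/D),
refused if too coarse) serves short-horizon drift runs. For still-air
capture-probability runs the horizon must reach ~5e4 s, so an adaptive mode
sets dt = ε(r−R)²/D with ε = 0.002 (per-step displacement ≈ 6% of the gap
to the absorber), clipped to [1e−5, 100] s; the dt floor dominates the
crossing bias, and 1e−5 s keeps the total bias ≲ 0.005 absolute — below
the 3·SE band at N = 20000. The horizon T = 5e4 s bounds the heavy-tail
truncation bias at ≈ 0.002–0.003. Convergence at the 1/√N rate and
agreement of the still-air hit-time distribution with the first-passage
law (Kolmogorov–Smirnov distance shrinking with N) are tested.

*Symbol trials.* Each trial samples the slot observation directly
(binomial signal, coin×binomial ISI, Gaussian noise) for every molecule,
scales by the absorption factor and applies the threshold-exclusion
decision. 1e5 trials reproduce the closed-form DER within
max(0.02, 3·SE) across k ∈ {1, 3} and SNR ∈ {5, 10, 20} at M q₁ ≥ 500.

Both simulators require a seed and are bit-for-bit reproducible.

## Experiment defaults and open parameters

Fixed study conditions: M = 0.0016 mg, R = 0.15 m, ω = τ = 2 s, φ = 0.5;
absorption sweeps use v = 3 m/s, D = 0.008 m²/s; detection experiments use
d = 1 m, v = 1 m/s, D_b1/D_b2 as above, SNR = 10. Parameters the study
leaves open are fixed once as the package's own choices: T_s = 2 s (equal
to the observation window, so the first detection window spans the arrival
peak), d = 1 m and ω = 2 s where unstated, and detection thresholds at the
interior optimum of the average-DER surface located by a 41×41 grid search
at the reference emission mass (the miss/false-alarm trade-off makes the
surface U-shaped in each threshold, so the optimum is interior). The
detection-range search scans 240 coarse distances over (0, 6] m and refines
the farthest threshold crossing by bisection to 1 mm.

Sweep outputs are tidy long-form CSV (`sweep_var, value, molecule, metric,
metric_value`) under a `# config_hash=…, seed=…` provenance header;
re-running a sweep with the same spec reproduces the file byte-for-byte.

## What the tests do and do not show

The suite validates *internal* correctness and the study's qualitative
structure: closed forms against independent quadrature/argmax/first-passage
oracles, conservation and linearity identities, Monte Carlo agreement, the
monotonicity findings (absorption falling with distance and φ, rising with
τ and M; DER falling with SNR and M; interior threshold optimum), DER
saturation at 1 below 3e-5 mg emissions, and a ≤ 0.3 m detection range at
the 2.1e−4 mg threshold. It does not validate the model against real
plants: ambient turbulence, ground boundaries, gravity, evaporation,
degradation, multi-compound co-release and temperature/humidity coupling
are all outside the model, and the v > 0 channel heuristic is known to
underestimate downwind capture (quantified above). Point-wise reproduction
of the published sweep curves is not attempted — they exist only as plotted
figures with several unstated parameters — so the structural and anchored
checks above stand in for them.
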