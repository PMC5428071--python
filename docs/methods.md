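# Methods

This note documents the models, estimators and numerical policies of
`polyfric`, and what the package's tests do and do not establish.

## The scientific question

The global reconfiguration time of an unfolded polypeptide — the relaxation
time τ_EE of its end-to-end distance — interpolates between two limits. In
the Rouse (solvent-friction) limit it tracks the time for the chain to
diffuse over its own size, τ_R = c⟨R²⟩/D_tr with c = π⁻²/3 for the slowest
Rouse mode. In the barrier-friction limit it tracks the hindered-rotation
time τ_dih of individual backbone dihedrals, which grows exponentially with
the rotation barrier ε and is independent of chain length. The package
measures both timescales in controlled simulations and fits the additive
interpolation

    τ_EE = a·τ_R + b·τ_dih,

where b·τ_dih is the internal-friction timescale. A chain-length-independent
b indicates that dihedral flips are concerted (crankshaft-like, local moves);
if instead every flip randomised the whole chain, τ_EE would fall as 1/N —
a contrast the package reproduces with its kinetic Monte Carlo chain.

## Models

### Coarse-grained Langevin chain (`chain`, `langevin`)

One bead per residue, reduced units σ = k_BT = ξ₀ = 1, time unit
τ₀ = σ²ξ₀/k_BT. Potential terms:

| term | form | default |
| --- | --- | --- |
| bond | ½ k_bond (r − σ)² | k_bond = 200 k_BT/σ² |
| bend | ½ k_bend (θ − θ₀)² | k_bend = 20 k_BT/rad², θ₀ = 100° |
| dihedral | ε(1 − cos 3φ)/2 | ε ∈ [0, 6] k_BT (the control variable) |
| excluded volume | A[(σ/r)¹² − (σ/r_c)¹²], r < r_c | A = 1 k_BT, r_c = 2σ |

The dihedral potential has three wells at φ = 0, ±120° separated by barriers
of exactly ε. Excluded volume acts between beads at least four bonds apart:
1-2 and 1-3 pairs are constrained by the bonded terms and 1-4 pairs by the
dihedral term (standard force-field exclusion); with θ₀ near 100-120° the
cis 1-4 distance would otherwise sit inside any physically sensible cutoff.

θ₀ is the calibrated parameter: it is set so that the *full* model (bending
plus excluded-volume swelling) has Kuhn length l_k = ⟨R²⟩/L ≈ 3σ at
desk-scale lengths, the stiffness of real polypeptides (three peptide bonds
per Kuhn segment). A scan over θ₀ gave l_k/σ = 4.0 at 120° and 2.97 at 100°
(N = 33); the default is therefore 100°. Note that excluded volume slightly
depletes the cis well (populations ≈ [0.29, 0.36, 0.36]); the exact 3-fold
symmetry holds only for the phantom variant (`CGChainConfig.ideal()`).

Dynamics are overdamped (free-draining, no hydrodynamic interactions),
integrated with Euler–Maruyama at dt = 5×10⁻⁴ τ₀. Accuracy is policed by a
dt-halving test on τ_EE rather than by a higher-order scheme. Noise comes
from a counter-based Philox generator keyed on the run seed, drawn in
(step, bead, coordinate) order as float32 (generation is twice as fast and
the rounding, ~10⁻⁹σ per step, is far below the thermal noise amplitude);
same-seed runs are bitwise identical. A run discards an equilibration
prefix (default 10% of the production length) before recording frames.

Initial conformations place all dihedrals exactly at well minima. For
N ≤ 35 the builder uses exact rejection sampling of the clash-constrained
rotational-isomeric ensemble; beyond that the acceptance rate decays
exponentially (chain attrition) and a sequential growth with per-bead
retries is used instead — slightly biased, but irrelevant after
equilibration.

### Rotational isomeric state chain (`rism`)

Dihedrals are the only degrees of freedom: each is an independent
continuous-time Markov chain on the three wells with all six pairwise rates
equal to k (exact event-driven simulation). Derived timescales: mean dwell
1/(2k); single-dihedral relaxation τ_dih = 1/(3k), the inverse of the
smallest nonzero eigenvalue of the 3×3 rate matrix, and exactly the integral
of C(t) = ⟨cos Δφ⟩ = e^(−3kt). Conformations are rebuilt from the state
vector by internal-coordinate growth with the same σ, θ₀ as the Langevin
chain; flipping one dihedral rigidly pivots the downstream part of the
chain, so a single flip decorrelates R on the scale of the whole chain —
this is what makes τ_EE ∝ 1/N for independent flips.

The memoryless-jump closed form used as the oracle for this picture is
⟨ΔR²(t)⟩ = (1 − e^(−νt))·⟨(R′ − R)²⟩ with ⟨(R′ − R)²⟩ = 2 Var(R) for
independent equilibrium draws, and every higher moment shares the same
(1 − e^(−νt)) time dependence. (Carrying the expectation through gives the
factor 2 on the variance; the direct jump simulation in the tests confirms
it.)

### Hall–Helfand 1D chain (`hall_helfand`)

N independent telegraph bonds jumping between two lengths at rate k per
direction. Two distinct "relaxation times" are exposed deliberately:
the diffusion-estimate composition ρ²/(2D) = τ_bond/2 (with D = NΔl²k/2,
ρ² = NΔl²/4, τ_bond = 1/(2k)), and the ACF-integral time, which is exactly
τ_bond because the end-to-end ACF is a single exponential with rate 2k.
They differ by a factor of two and answer different questions; conflating
them would silently corrupt any comparison.

## Estimators (`correlators`)

* **Integral relaxation time.** τ = ∫C(t)dt / C(0) with the biased (1/M)
  autocovariance (positive semi-definite by construction), trapezoid
  integration, truncated at the first lag where C/C(0) < 0.01 or the first
  zero crossing (whichever is earlier), capped at one fifth of the series
  length. On Ornstein–Uhlenbeck fixtures the policy recovers the true
  correlation time to within ~3% (the truncated tail accounts for ~1%); a
  curve that never decays below the level is flagged unconverged.
  The dihedral correlator ⟨cos[φ(t+s) − φ(s)]⟩ uses per-lag (unbiased)
  origin averaging so that C(0) = 1 exactly.
* **MSD moments and α.** ⟨|ΔX(t)|^(2n)⟩ on a log-spaced lag grid with dense
  coverage of the first ten lags. α is the log-log slope of the n = 1
  moment between two samples and the lag where the MSD first reaches 10% of
  its plateau (taken as 2·Var for a stationary scalar). The high-barrier
  MSD is not a clean power law — the local slope falls from ~0.76 in this
  short-time window through ~0.6 at intermediate lags before saturating —
  so the reported α is attached to this specific window; the window edges
  are parameters.
* **Translational diffusion.** Centroid MSD slope / 6, fitted with
  relative-error weights over short lags (up to 1/500 of the series
  duration), because the sampling error of an MSD point grows as
  √(lag/duration). A fit with weighted R² < 0.99 is flagged non-diffusive.
* **Flip detection.** Each well owns a core sector shrunk by a hysteresis
  buffer (default 20°); a flip fires at the first sample inside a
  *different* well's core, suppressing barrier-recrossing double counts.
  Event counts are invariant under time reversal, and increasing the buffer
  never increases the count.
* **Pair lag test.** For each flip of dihedral i whose next flip within the
  pair belongs to j (no intervening i-flip), the lag to that flip of j.
  This competing-risks lag is exactly exponential with rate 1/τ_i + 1/τ_j
  under independent Poisson flipping (τ's from the dihedral ACF, not from
  mean dwells); the unrestricted "next j-flip" lag would instead be
  exponential with rate 1/τ_j alone. The two-sided KS p-value is reported
  together with a signed statistic (D⁺ − D⁻), positive when short lags are
  over-represented.
* **Crossing time.** Besides the integral τ, every ACF exposes the
  1/e-crossing time of C(t)/C(0). For the RIS chain this isolates the
  pivot-driven global decorrelation (rate ∝ 2kN) from a small,
  N-independent tail contributed by sequence-local bond pairs; the 1/N
  scaling of the reconfiguration time is a statement about the dominant
  decay and is measured with the crossing time (the integral flattens the
  apparent slope to ≈ −0.85 over N = 8–64).

## Run policy (`pipeline`)

A regime sweep gives each (N, ε) condition a pilot run (default 10⁶ steps)
to estimate τ_EE, then a production length of max(100·τ_EE, 10⁷ steps)
capped by a configurable budget, with unconverged ACFs flagged and excluded
from fits. Reported values average several seeds (default 4); the quoted
error is the seed-to-seed standard error. The interpolation fit is linear
least squares without intercept, each record weighted by 1/SE(τ_EE) (3% of
τ_EE when no seed spread is available); the fit refuses rank-deficient
designs (all records in one regime) and flags a b whose standard error
exceeds half its value. Desk-scale studies use the reduced grid
N ∈ {10, 20, 33}, ε ∈ {0, 2, 4, 5} with ~10⁶–10⁷-step runs; the full grid
N ∈ {10, 20, 33, 66}, ε ∈ {0…6} is available behind the same interface.

## What the synthetic fixtures do and do not show

The estimator suite is validated on processes with known answers (OU,
rotational diffusion, fractional Brownian motion, telegraph chains,
memoryless jumps). These fixtures share the stationarity and uniform
sampling of the real trajectories but none of their non-exponential ACF
tails, so estimator accuracy quoted on fixtures (e.g. 5% on OU) is a lower
bound on the uncertainty for chain observables; seed-to-seed spread is the
operative error there.

## Numerical choices and degenerate inputs

Collinear bead triples make the torsion undefined (error); exactly straight
bends contribute zero force (measure-zero set). Constant series raise a
degeneracy error in the scalar/vector ACF; a frozen dihedral yields C ≡ 1
and is flagged unconverged. The integrator traps non-finite coordinates or
bonds stretched beyond 5σ and reports the failing step. The blow-up check
runs one step behind the update inside the compiled loop; the end state is
re-validated in Python.

## Known limitations

* The coefficients of the ratio claims (τ_V/τ_EE ≈ 3, τ_EE ≈ 0.5 τ_V,
  τ_V ≈ 0.8 τ_R) are definition-sensitive. For a strictly Gaussian chain
  the *integral* estimator gives τ_EE/τ_V ≈ 0.41 and τ_V ≈ 0.82 τ_R
  (quadrature over the Rouse mode sum), and the simulated Gaussian phantom
  (`CGChainConfig.gaussian()`, harmonic bonds only) reproduces both
  (≈ 0.43 and ≈ 0.78). Keeping the bending stiffness shifts τ_V/τ_R up to
  ≈ 1.0 (local stiffness loads the slowest mode), and excluded volume
  raises τ_V/τ_EE to ≈ 5–7: τ_V grows with the swollen ⟨R²⟩ while the
  distance ACF of the self-avoiding chain decays relatively faster. The
  Rouse-reference ratios are therefore quoted on the Gaussian phantom, the
  vector/distance contrast of the full chain separately.
* At ε ≤ 6 and the calibrated geometry, τ_dih (≈ 15–35 τ₀ at ε = 5–6)
  exceeds τ_R only for short chains, so the deep barrier-friction regime is
  reached for N ≲ 20 but not for N = 33 within the default grid.
* Chain-end dihedrals relax several times faster than interior ones here —
  more than the factor ≲ 2 seen for stiffer peptide models — and the
  per-position max/min spread is seed-noisy because the extreme values come
  from single noisy ACF integrals.
* The crossing where the end-to-end *vector* time drops below the distance
  time deep in the barrier regime is not reached within ε ≤ 6 at this
  geometry: chain rotation (τ_V ≈ 30 τ₀ at N = 20) stays slower than the
  distance relaxation because τ_dih does not yet dominate the rotational
  timescale.
* No hydrodynamic interactions, no solvent viscosity variable, no side
  chains or sequence heterogeneity, no attractive interactions: the package
  isolates the barrier-friction mechanism and is not a folding model.
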