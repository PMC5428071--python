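# polyfric

Internal friction in unfolded polypeptides: coarse-grained simulations and
analysis of the transition from solvent-dominated (Rouse) to
dihedral-barrier-dominated chain dynamics.

## The problem

The reconfiguration time of an unfolded protein — the relaxation time
τ_EE of its end-to-end distance — is not set by solvent friction alone.
Hindered rotations of backbone dihedral angles, which cross barriers of a
few k_BT, add an *internal friction* timescale that survives extrapolation
to zero solvent viscosity. `polyfric` provides the models and estimators to
study this mechanism quantitatively:

* a **bead-spring homopeptide** (one bead per residue; harmonic bonds and
  bends, 3-fold hindered-rotation potential V_dih = ε(1 − cos 3φ)/2,
  repulsive r⁻¹² excluded volume) integrated by overdamped Langevin
  dynamics with a compiled inner loop;
* a **rotational isomeric state (RIS) kinetic Monte Carlo** chain whose
  dihedrals are independent 3-state Markov jumpers — the null model of
  *uncorrelated* dihedral rotations;
* the **Hall–Helfand 1D bond-jump chain** with its closed-form diffusion
  estimate ρ²/(2D) = τ_bond/2;
* an observable layer: integral autocorrelation relaxation times (scalar,
  vector, dihedral), MSD moments and subdiffusion exponents, dihedral flip
  detection with hysteresis, dwell/Poisson statistics and pair lag-time
  correlation tests;
* a pipeline that sweeps chain length N and barrier height ε and fits the
  additive interpolation

      τ_EE = a·τ_R + b·τ_dih,

  where τ_R = c⟨R²⟩/D_tr (c = π⁻²/3) is the Rouse time and b·τ_dih is the
  internal-friction timescale. A b independent of N is the fingerprint of
  concerted, crankshaft-like dihedral moves; independent flips would
  instead give τ_EE = 3τ_dih/(2N), falling with chain length.

All quantities are in reduced units: σ (bond length) = k_BT = ξ₀ = 1, time
unit τ₀ = σ²ξ₀/k_BT.

## Worked example

```python
import polyfric as pf

config = pf.CGChainConfig(N=20, eps_dih=3.0)
traj   = pf.run_langevin(config, n_steps=4_000_000, seed=1, stride=100)

obs = pf.analyze_trajectory(traj)
ref = pf.rouse_time(config, obs["R2_mean"])
print(obs["tau_EE"], obs["tau_V"], obs["tau_dih"], ref.tau_R)
```

Running `python examples/01_simulate_and_relaxation_times.py` (which is
this computation) prints:

```
N = 20, dihedral barrier = 3.0 kBT
<R^2>   = 45.7 sigma^2  (Kuhn length 2.40 sigma)
tau_EE  = 6.08 tau0   (end-to-end distance)
tau_V   = 53.33 tau0   (end-to-end vector)
tau_dih = 2.60 tau0   (interior dihedrals)
tau_R   = 30.85 tau0   (Rouse reference, c = 1/(3 pi^2))

tau_EE/tau_R = 0.2 and tau_EE/tau_dih = 2.34 - at this barrier both
solvent and barrier friction contribute.
```

τ_EE sits well below the Rouse reference (the chain is short, and the
distance relaxes faster than the vector) while τ_dih is still fast; raising
ε to 5–6 k_BT makes τ_dih overtake τ_EE, the barrier-friction signature. The other examples
cover the interpolation fit (`02`), the 1/N scaling of the
independent-flip RIS chain (`03`), the Hall–Helfand closed forms (`04`),
flip statistics and pair lag correlations (`05`), and subdiffusion
diagnostics (`06`).

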