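"""Independent dihedral flips make the reconfiguration time shrink with N.

Runs the rotational-isomeric-state kinetic Monte Carlo chain (dihedrals as
the only degrees of freedom, each an independent 3-state Markov jumper at
rate k per transition) for several chain lengths, and shows tau_EE ~ 1/N —
the opposite of the length-independent barrier-friction time observed for
the Langevin chain.  This contrast is the discriminator between independent
and concerted dihedral rotations.
"""

import numpy as np

import polyfric as pf

print("single-dihedral relaxation time tau_dih = 1/(3k); here k = 1, tau_dih = 1/3\n")
taus = {}
for N in (8, 16, 32, 64):
    # sampling interval scaled with the expected time so resolution bias is
    # N-independent; the 1/e decay time isolates the pivot-driven decay
    tau_pred = 1.0 / (2 * N)
    cfg = pf.RismConfig(N=N, k=1.0, t_max=3000.0 * tau_pred, record_dt=tau_pred / 10)
    path = pf.run_rism_kmc(cfg, seed=N)
    _, r = pf.rism_end_to_end_series(path)
    taus[N] = pf.acf_scalar(r, dt=cfg.record_dt).crossing_time()
    pred = pf.independent_flip_time(cfg.tau_dih, N)
    print(f"N={N:3d}: tau_EE = {taus[N]:.4f}  (memoryless-flip prediction 3*tau_dih/(2N) = {pred:.4f})")

slope = np.polyfit(np.log(list(taus)), np.log(list(taus.values())), 1)[0]
print(f"\nlog-log slope of tau_EE vs N: {slope:.2f} (independent flips predict -1)")
print("A real peptide shows no such decrease: its flips must be concerted.")
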