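"""Subdiffusive end-to-end dynamics and the moment-ratio diagnostic.

Computes displacement moments <dR^(2n)(t)> of the end-to-end distance for a
high-barrier chain and fits the short-time exponent alpha (<dR^2> ~
t^alpha; alpha < 1 means subdiffusion, i.e. memory).  Also demonstrates the
memoryless-jump fingerprint on a synthetic series: all moments share one
saturation curve (1 - e^{-nu t}), unlike diffusion where <dR^4>/<dR^2>^2
stays constant.
"""

import numpy as np

import polyfric as pf
from polyfric import synthetic as syn

config = pf.CGChainConfig(N=20, eps_dih=5.0)
traj = pf.run_langevin(config, n_steps=10_000_000, seed=11, stride=100)
r = traj.end_to_end_distance()
res = pf.msd_moments(r, orders=(1, 2), dt=traj.frame_dt)
print(f"N={config.N}, eps={config.eps_dih} kBT: short-time exponent alpha = {res.alpha:.2f} "
      f"over lags {res.fit_window[0]:.2f}-{res.fit_window[1]:.2f} tau0")
print("alpha < 1: the end-to-end distance is subdiffusive (non-Markov memory).")

nu = 0.5
x = syn.memoryless_jump_series(200_000, 0.05, nu=nu, seed=12)
model = pf.MemorylessModel(nu=nu, R_mean=float(x.mean()), R_var=float(x.var()))
ms = pf.msd_moments(x, orders=(1, 2), dt=0.05)
sel = (ms.lags > 0.2) & (ms.lags < 10)
theory = pf.memoryless_msd_theory(model, ms.lags[sel])
err = np.max(np.abs(ms.moments[1][sel] - theory["msd"]))
ratio = ms.moments[2][sel] / ms.moments[1][sel] ** 2
print(f"\nmemoryless-jump series: max |MSD - (1-e^-nu t)*2Var| = {err:.3f} "
      f"(amplitude {theory['msd'].max():.2f})")
print(f"<dR^4>/<dR^2>^2 varies by x{ratio.max()/ratio.min():.1f} across lags "
      "(constant for diffusion): single-jump memory loss is distinguishable.")
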