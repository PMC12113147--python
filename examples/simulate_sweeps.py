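"""Forward simulation: how polydispersity and the inner shell shape the curve.

Sweeps the core-size spread sigma and the inner-shell thickness t1 around the
base geometry (R0 = 25 nm core, 2 / 0.3 / 4 nm shells) and prints the two
signatures a practitioner reads off such curves: the number of form-factor
fringes (fewer = more polydisperse) and the forward intensity (lower when the
negative-SLD inner shell thickens).
"""

import numpy as np

from lnpsaxs import SweepSpec, local_maxima, run_sweep

print("polydispersity sweep (R0 = 25 nm):")
for sigma, curve in run_sweep(SweepSpec(vary="sigma", values=[1, 2, 3, 4, 5, 6])):
    n_fringes = len(local_maxima(curve))
    print(f"  sigma = {sigma:.0f} nm  (sigma/R0 = {sigma/25:.2f}):"
          f" {n_fringes} distinct oscillation maxima")
print("-> fringes wash out as sigma/R0 grows; none remain beyond ~0.2\n")

print("inner-shell thickness sweep (rho_1 = -0.01):")
for t1, curve in run_sweep(SweepSpec(vary="t1", values=[1, 2, 3, 4])):
    i_fwd = np.interp(0.08, curve.q, curve.intensity)
    print(f"  t1 = {t1:.0f} nm: I(q=0.08 nm^-1) = {i_fwd:.3g}")
print("-> a thicker negative-contrast inner shell cancels more of the core's"
      " forward scattering")
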