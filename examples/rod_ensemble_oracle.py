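"""Check the analytic speckle model against a microscopic rod ensemble.

Simulates explicit rods (Brownian positions + rotational diffusion on the
sphere) and compares the empirical co- and cross-polarized field
autocorrelations with the closed-form rod scattering model and with the
fast analytic-process backend.
"""

import numpy as np

from dsoct import OpticalConfig, normalized_autocorrelation, simulate_process, simulate_rod_ensemble

optics = OpticalConfig()  # 62.5 kHz, 800 nm, n = 1.33
dt_true, dr_true = 2.0, 2000.0
q = optics.q_per_um
per = optics.aline_period_s

hh_r, hv_r = simulate_rod_ensemble(400, dt_true, dr_true, optics, 30_000, seed=3)
hh_p, hv_p = simulate_process(dt_true, dr_true, optics, 30_000, seed=3)

kmax = 40
g = {
    "rod HH": normalized_autocorrelation(hh_r, per, kmax=kmax).g,
    "rod HV": normalized_autocorrelation(hv_r, per, kmax=kmax).g,
    "process HH": normalized_autocorrelation(hh_p, per, kmax=kmax).g,
    "process HV": normalized_autocorrelation(hv_p, per, kmax=kmax).g,
}
lags = per * np.arange(1, kmax + 1)
ana_hh = np.exp(-q * q * dt_true * lags) * (5 / 9 + 4 / 9 * np.exp(-6 * dr_true * lags))
ana_hv = np.exp(-(q * q * dt_true + 6 * dr_true) * lags)

print("max |empirical - analytic| over the first 40 lags:")
print(f"  rod ensemble HH: {np.abs(g['rod HH'] - ana_hh).max():.3f}")
print(f"  rod ensemble HV: {np.abs(g['rod HV'] - ana_hv).max():.3f}")
print(f"  process      HH: {np.abs(g['process HH'] - ana_hh).max():.3f}")
print(f"  process      HV: {np.abs(g['process HV'] - ana_hv).max():.3f}")
print("Both backends track the two-exponential (HH) and single-product "
      "(HV) rod model within Monte-Carlo error (~a few times 0.01).")
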