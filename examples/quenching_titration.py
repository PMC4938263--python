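"""Fit a fluorescence-quenching titration and read off Ksv, kq, Kb and n.

Builds a noiseless titration of a 5 uM protein with 0-50 uM quencher
following the static-quenching law F0/F - 1 = Kb [Q]^n, then fits both
linearisations.  Ksv measures quenching efficiency; kq = Ksv/tau0 far above
the diffusion limit (2e10 M^-1 s^-1) indicates ground-state complex
formation; Kb and n characterise the binding equilibrium.
"""

import numpy as np

from specbind import TitrationSeries, modified_sv_fit, stern_volmer_fit

q = np.arange(0, 55e-6, 5e-6)
f0 = 1000.0
kb, n = 3.14e5, 1.1
f = f0 / (1.0 + np.where(q > 0, kb * q**n, 0.0))
series = TitrationSeries(q, f, f0, protein_label="HSA", temperature_K=298.0)

sv = stern_volmer_fit(series, tau0_s=1e-9)
binding = modified_sv_fit(series)

print(f"Ksv = {sv.ksv_M_inv:.3e} M^-1  (intercept {sv.intercept:.3f}"
      f"{', flagged: departs from 1 because n != 1' if sv.intercept_flagged else ''})")
print(f"kq  = {sv.kq_M_inv_s_inv:.3e} M^-1 s^-1  "
      f"(diffusion limit 2.0e10 -> static quenching)")
print(f"Kb  = {binding.kb_M_inv:.3e} M^-1,  n = {binding.n_sites:.3f}")
print("The double-log fit recovers the generating Kb and n exactly; on real")
print("data n near 1 indicates a single independent binding site.")
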