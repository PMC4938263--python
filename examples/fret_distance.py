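"""Donor-acceptor distance from spectral overlap (FRET).

Generates a Gaussian tryptophan-like emission band and an overlapping
acceptor absorptivity band, computes the overlap integral J, the Förster
radius R0 (kappa^2 = 2/3, n = 1.336, phi = 0.15), the transfer efficiency
from a 71% quench at equimolar donor:acceptor, and the distance r, checking
it lies inside the reliable window 0.5 R0 < r < 1.5 R0.
"""

from specbind import fret_analysis, generate_overlap_pair

donor, acceptor, _ = generate_overlap_pair(
    donor_center_nm=340, donor_sigma_nm=15,
    acceptor_center_nm=330, acceptor_sigma_nm=12,
    epsilon_peak_M_inv_cm_inv=4000)

res = fret_analysis(donor, acceptor, f=290.0, f0=1000.0,
                    range_nm=(265, 415))
print(f"J  = {res.j_nm4_M_inv_cm_inv:.3e} nm^4 M^-1 cm^-1  "
      f"(= {res.j_cm3_M_inv:.3e} cm^3 M^-1)")
print(f"R0 = {res.r0_nm:.2f} nm")
print(f"E  = {res.efficiency:.2f}  ->  r = {res.r_nm:.2f} nm")
print(f"inside Förster window (0.5 R0 < r < 1.5 R0): {res.forster_window_ok}")
print("r of this magnitude confirms non-radiative energy transfer from the")
print("protein's tryptophan to the bound ligand is geometrically plausible.")
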