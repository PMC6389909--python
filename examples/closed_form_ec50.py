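"""The closed-form EC50 <-> K_d relations at published operating points.

In the coupled-equilibrium model the titration midpoint obeys
EC50 = K_d/(1 - f_u0) + [P]_T/2 exactly, where f_u0 = K_U/(1+K_U) is the
ligand-free fraction unfolded.  Two consequences:

* a quick Hill-style EC50 estimate converts directly to K_d, and
* when EC50 approaches [P]_T/2 the midpoint is set by stoichiometry and
  K_d can only be bounded.
"""

from dsf_isofit import StoichiometricRegimeError, ec50_from_kd, kd_from_ec50

uM = 1e-6

# maltose/MBP at 53 C: EC50 = 6.8 uM (Hill estimate), K_U = 1.3, 2 uM protein
f_u0 = 1.3 / (1 + 1.3)
kd = kd_from_ec50(6.8 * uM, 2 * uM, f_u0)
print(f"MBP/maltose 53 C: EC50 6.8 uM, K_U 1.3  ->  K_d = {kd / uM:.2g} uM")

# the stoichiometric reporting threshold at 2 uM protein, half unfolded
ec50 = ec50_from_kd(0.5 * uM, 2 * uM, 0.5)
print(f"K_d 0.5 uM at f_u0 = 0.5, [P]_T = 2 uM  ->  EC50 = {ec50 / uM:.2g} uM")
print("so any EC50 below 2 uM at this protein concentration is reported "
      "as K_d < 0.5 uM")

# below [P]_T/2 the conversion is refused
try:
    kd_from_ec50(0.9 * uM, 2 * uM, 0.5)
except StoichiometricRegimeError as exc:
    print(f"EC50 0.9 uM: {exc}")
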