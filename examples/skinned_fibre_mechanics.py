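"""Single skinned-fibre analysis: stiffness/strain from the T1 relation,
the Y0-T0 regression across calcium levels, force-pCa sensitivity, and the
passive Young's modulus.
"""

import numpy as np

from fibractin import (
    GeneratorConfig,
    elliptical_csa,
    fit_force_pca,
    fit_t1_relation,
    gen_force_pca,
    passive_young_modulus,
    regress_strain_force,
)

print(f"fibre CSA (60 x 40 um ellipse): {elliptical_csa(60, 40):.0f} um^2\n")

# T1 relations at three calcium levels: length steps of -3..+3 nm per
# half-sarcomere against end-of-step force (relative to isometric).
steps = np.linspace(-3, 3, 7)
t0_levels = [0.4, 0.7, 1.0]  # relative isometric force at each pCa
y0_values = []
for t0 in t0_levels:
    t1 = t0 * (1.0 + steps / 4.0)  # cross-bridge strain of 4 nm/hs
    rel = fit_t1_relation(steps, t1)
    y0_values.append(rel.y0_nm_hs)
    print(f"T0={t0:.1f}: stiffness {rel.slope:.3f} /nm, Y0 {rel.y0_nm_hs:.2f} nm/hs")

reg = regress_strain_force(t0_levels, y0_values)
print(f"Y0-T0 regression: Cf = {reg.cf:.3f}, s0 = {reg.s0:.3f} nm/hs")
print("A T0-independent Y0 (Cf ~ 0) means the strain per attached motor,")
print("and hence the force per motor, does not change with activation.\n")

# Force-pCa relation
pca_pts = gen_force_pca(2.8, 5.85, GeneratorConfig(seed=3, noise_sd=0.02))
pfit = fit_force_pca(pca_pts["pca"], pca_pts["t_rel"])
print(f"force-pCa: nH = {pfit.n_h:.2f} (cooperativity), pK = {pfit.pk:.2f}"
      " (Ca sensitivity)")

# Passive stretch to failure
sl = np.arange(2.4, 3.81, 0.1)
stress = 8.0 * (np.exp(1.8 * (sl - 2.4)) - 1.0)  # kN/m2
passive = passive_young_modulus(sl, stress, sl_slack_um=2.4)
print(f"passive modulus at sl 3.0 um: {passive.e_per_um:.1f} kN/m2 per um"
      f" ({passive.e_per_strain:.1f} kN/m2 per unit strain), "
      f"failure at {passive.failure_sl_um:.2f} um")
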