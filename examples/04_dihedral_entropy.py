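"""Torsional entropy difference between a floppy and an ordered ensemble.

Builds two synthetic dihedral ensembles — coil torsions uniform on the
circle, globule torsions von Mises concentrated — and estimates
dS_pol = S_globule - S_coil per torsion with the periodic KDE, against
the Bessel-function closed form.
"""

import numpy as np
import pandas as pd

from cgtkit.constants import R_GAS
from cgtkit.entropy import delta_entropy, von_mises_entropy

rng = np.random.default_rng(0)
n, k, kappa = 20_000, 17, 2.0

angles = np.vstack(
    [rng.uniform(-np.pi, np.pi, (n, k)), rng.vonmises(0.0, kappa, (n, k))]
)
df = pd.DataFrame({f"phi_{i + 1}": angles[:, i] for i in range(k)})
df.insert(0, "replica", 0)
coil_mask = np.arange(2 * n) < n

res = delta_entropy(df, coil_mask, ~coil_mask, min_frames=100, loo=False)
expected = k * (von_mises_entropy(kappa) - R_GAS * np.log(2 * np.pi))
print(f"S_coil    = {res.S_coil:7.2f} J/(mol K)  "
      f"(closed form {k * R_GAS * np.log(2 * np.pi):.2f})")
print(f"S_globule = {res.S_globule:7.2f} J/(mol K)  "
      f"(closed form {k * von_mises_entropy(kappa):.2f})")
print(f"dS_pol    = {res.dS_pol:7.2f} J/(mol K)  (closed form {expected:.2f})")
print(f"T*dS_pol  = {res.dS_pol * 300 / 1000:7.2f} kJ/mol at 300 K")

print(
    "\ndS_pol < 0: the ordered (globule-like) ensemble has lower torsional\n"
    "entropy than the floppy (coil-like) one; multiplying by T expresses\n"
    "its contribution to the transition free energy."
)
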