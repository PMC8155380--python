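"""Two-stage background estimation: solid harmonics + external dipoles.

A synthetic field combines a smooth 5th-order harmonic component with the
dipole field of a point source outside the support.  Both stages are
fitted on the trusted evaluation area only, then *evaluated* on the full
support — the extrapolation that later repairs corrupted rim phase.
"""

import numpy as np

from refrase import fit_external_dipoles, fit_ssh, dipole_background_field, hz_per_ppm
from refrase.background import PaddedDipoleConv
from refrase.harmonics import evaluate_ssh_field, n_basis

shape = (48, 48, 48)
g = np.ogrid[:48, :48, :48]
r2 = sum((gi - 23.5) ** 2 for gi in g)
m_ea = r2 <= 16.0**2          # trusted inner region
m_max = r2 <= 20.0**2         # full support to extrapolate onto

rng = np.random.default_rng(4)
coeffs = np.zeros(n_basis(5))
for l, std in enumerate([1, 1, 2.5e-3, 1.25e-4, 1.25e-7, 1.25e-8]):
    coeffs[l * l:(l + 1) * (l + 1)] = rng.normal(0, std, 2 * l + 1)
b_harm = evaluate_ssh_field(shape, coeffs)

conv = PaddedDipoleConv(shape)
src = np.zeros(shape)
src[44, 24, 20] = 6.0          # external point source, chi in ppm
b_true = b_harm + hz_per_ppm(7.0) * conv(src)

model_ssh, b_ssh = fit_ssh(b_true, m_ea, order=5, m_eval=m_max)
resid = b_true - b_ssh
model_dip = fit_external_dipoles(resid, m_ea, m_max, lambda_ext=1e-3, warn=False)
b_dip = dipole_background_field(model_dip, m_max, sigma=0.0, conv=conv)
b_bg = b_ssh + b_dip

for name, mask in (("m_EA (fit region)", m_ea), ("m_max (extrapolated)", m_max)):
    rel = np.sqrt(np.mean((b_bg - b_true)[mask] ** 2) / np.mean(b_true[mask] ** 2))
    print(f"relative RMSE of background estimate on {name}: {100 * rel:.2f}%")
# The fit region is reproduced at the sub-percent level; the extrapolated
# rim estimate is coarser, but it only needs to pull the residual phase
# gradients back under the Nyquist limit for the rim to become
# unwrappable — exactness is recovered over the following iterations.
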