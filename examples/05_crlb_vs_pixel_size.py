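"""How localization accuracy degrades with pixel size.

The practical-model Fisher information for a stationary emitter is the
multinomial form L * sum_k (dp_k/dtheta)^T (dp_k/dtheta) / p_k over the
pixel-hit probabilities. Coarser pixels blur the photon positions and
inflate the bound toward (and beyond) the unpixelated limit sigma/sqrt(L).
"""

import numpy as np

import pixtraj as px

spec = px.ParameterSpec(names=("x0", "y0"))
print(f"{'pixel (um)':>10} {'CRLB sd (nm)':>13}")
for width in (0.5, 2.0, 6.5, 13.0, 26.0):
    n = int(round(390.0 / width))  # keep the detector area fixed
    bundle = px.example_bundle(D=0.0, f=0.0, pixel_um=width, n_pixels=n,
                               n_photons=3)
    sd_nm = px.fim_practical(bundle, spec, L=3).crlb_sd[0] * 1e3
    print(f"{width:>10.1f} {sd_nm:>13.2f}")
fund = px.fim_fundamental_conditional(
    px.example_bundle(D=0.0, f=0.0, n_photons=3), spec, L=3).crlb_sd[0] * 1e3
print(f"{'unpixelated':>10} {fund:>13.2f}")
# As the pixels shrink the practical bound converges to the fundamental
# sigma/sqrt(L) = 57.74 nm; at 26 um pixels (2.6 PSF widths) pixelation
# costs ~15% in accuracy.
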