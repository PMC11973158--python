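"""The k-space data-consistency step, in isolation.

Data consistency overwrites the predicted spectrum with the measured
samples wherever data were acquired, so the final image can never
contradict the acquisition.  An untrained (zero-weight) network therefore
reproduces the zero-filled reconstruction exactly.
"""

import numpy as np

from fourierpd import (
    PhantomConfig,
    data_consistency,
    fft2c,
    ifft2c,
    make_complex_phantom,
    make_varden1d_mask,
    reconstruct,
    undersample,
)
from fourierpd.models import FourierPD, ReconModelConfig

truth = make_complex_phantom(PhantomConfig(grid_size=64, seed=3))
mask = make_varden1d_mask((64, 64), 0.25, seed=1)
measured = undersample(fft2c(truth), mask)

# a deliberately wrong "prediction": pure noise
rng = np.random.default_rng(0)
noise = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
fixed = data_consistency(noise, measured, mask)
residual = np.abs((fft2c(fixed) - measured) * mask.grid).max()
print(f"k-space residual at acquired locations: {residual:.2e}")  # ~1e-15

model = FourierPD(ReconModelConfig(n_iterations=3, n_filters=8, seed=0))
model.zero_weights()
out = reconstruct(model, measured, mask)
zf = ifft2c(measured)
print(f"zero-weight model vs zero-filled: max difference {np.abs(out - zf).max():.2e}")
# Both numbers sit at floating-point round-off: acquired data are kept
# verbatim, and with no learned weights the pipeline is the identity on
# the zero-filled image.
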