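"""Infer a personalized network for every sample and inspect a switched edge.

A step-profile edge is absent below the modulator changepoint and strong
above it. The Gaussian-kernel-weighted recursive elastic net fits one
regression per (target, sample), so the fitted coefficient tensor should show
the edge switching on along the modulator axis — and stay exactly zero for
edges that do not exist.
"""

import numpy as np

from netten.kernel_net import KernelConfig, PenaltySpec, build_network_tensor
from netten.pipeline import auto_bandwidth
from netten.simulate import CoefficientProfile, NoiseSpec, generate_dataset

profiles = {(0, 0): CoefficientProfile("step", baseline=0.0, shifted=2.0)}
truth = generate_dataset(n=150, q=4, p=2, profiles=profiles,
                         noise=NoiseSpec(sigma=0.1, seed=2), seed=1)
data = truth.to_expression_dataset()

b = auto_bandwidth(data.modulator)
tensor = build_network_tensor(data, KernelConfig(bandwidth=b), PenaltySpec())
print(f"coefficient tensor: {tensor.shape} (targets x regulators x samples)")
print(f"kernel bandwidth b = {b:.3f}")

m = truth.modulator
est = tensor.coefficients[0, 0, :]
low, high = m < -0.4, m > 0.4
print(f"switched edge T000 <- R000 (truth: 0 below m=0, 2 above):")
print(f"  mean estimate at m < -0.4: {est[low].mean():+.3f}")
print(f"  mean estimate at m > +0.4: {est[high].mean():+.3f}")
null_cells = np.concatenate([tensor.coefficients[0, 1:, :].ravel(),
                             tensor.coefficients[1, :, :].ravel()])
print(f"nonexistent edges fitted exactly to zero: {np.mean(null_cells == 0):.1%}")
# The estimate tracks the regime-specific truth on each side of the
# changepoint, and the penalty keeps absent edges at exactly zero, which is
# what makes the later binary-adjacency comparisons meaningful.
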