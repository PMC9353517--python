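"""Run the ResNet-FPN-ED backbone and inspect the feature pyramid.

Prints the adaptive ECA kernel widths for the full-scale stage channel
counts, then forwards a random image through the CPU-sized preset and prints
the P2..P6 shape/stride contract.  Every level carries the same channel
width; spatial sides halve level to level; P6 is a stride-2 pool of P5.
"""

import numpy as np

from vineseg import nn
from vineseg.backbone import BackboneED, eca_kernel_size

print("adaptive channel-attention kernel widths psi(C) (gamma=2, b=1):")
for C in (256, 512, 1024, 2048):
    print(f"  C={C:5d} -> k={eca_kernel_size(C)}")

rng = np.random.default_rng(0)
backbone = BackboneED.test_scale(rng=rng)
image = nn.Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
pyramid = backbone(image)

print("\nfeature pyramid for a 128x128 input (test-scale preset):")
for name in pyramid.names:
    n, c, h, w = pyramid[name].shape
    print(f"  {name}: {h:3d} x {w:3d} x {c}  (stride {pyramid.strides[name]})")
# The top-down fusion upsamples with Dense Upsampling Convolution (a 3x3
# convolution to C*r^2 channels followed by the sub-pixel rearrangement),
# so the upsampler is learnable rather than fixed nearest-neighbour.
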