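"""Parameter and multiply counts: standard vs depthwise separable vs MDConv.

The depthwise-separable factorization reduces the multiply count by the
factor 1/N + 1/Dk^2; MDConv keeps depthwise cost while mixing kernel
sizes across channel groups.
"""

import numpy as np

from histotex import ConvSpec, MDConvSpec, conv_costs, dsc_params, \
    mdconv_forward, standard_conv_params
from histotex.mdconv import init_mdconv_weights

spec = ConvSpec(Dk=3, M=16, N=32, DF=8)
std, dsc, ratio = conv_costs(spec)
print(f"standard conv:  {standard_conv_params(spec):>6d} params, {std:>7d} multiplies")
print(f"separable conv: {dsc_params(spec):>6d} params, {dsc:>7d} multiplies")
print(f"multiply ratio {ratio:.6f} = 1/N + 1/Dk^2 = {1/32 + 1/9:.6f}")

# a 2-group mixed depthwise convolution: 3x3 kernels on the first half of
# the channels, 5x5 on the second, channel order preserved
md = MDConvSpec(M=4, groups=(2, 2), kernel_sizes=(3, 5))
rng = np.random.default_rng(0)
fm = rng.random((4, 8, 8))
out = mdconv_forward(fm, md, init_mdconv_weights(md, rng))
print(f"MDConv output shape {out.shape} (same channels, same resolution)")
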