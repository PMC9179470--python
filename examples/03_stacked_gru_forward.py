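"""One stacked-GRU forward pass, step by step.

A feature vector is chunked into an ordered sequence; each GRU layer
consumes the layer below at the same time step, and the top layer's final
hidden state feeds a softmax head.
"""

import numpy as np

from histotex import GRULayerParams, featuremap_to_sequence, gru_cell_step, \
    sgru_forward

rng = np.random.default_rng(0)

# a length-12 feature vector becomes a 4-step sequence of 3-vectors
features = rng.normal(size=12)
sequence = featuremap_to_sequence(features, chunk=3)
print(f"sequence shape: {sequence.shape} (t steps x chunk)")

# one cell step: update/reset gates in (0,1), candidate in (-1,1)
layer = GRULayerParams.init(hidden=4, inp=3, rng=rng)
u, r, c, h = gru_cell_step(sequence[0], np.zeros(4), layer)
print(f"update gate {np.round(u, 3)}")
print(f"reset gate  {np.round(r, 3)}")
print(f"candidate   {np.round(c, 3)}")

# full 2-layer stack + softmax head over 5 classes
stack = [layer, GRULayerParams.init(hidden=4, inp=4, rng=rng)]
head_w = rng.normal(size=(5, 4))
probs = sgru_forward(sequence, stack, head_w, np.zeros(5))
print(f"class probabilities {np.round(probs, 4)} (sum = {probs.sum():.12f})")
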