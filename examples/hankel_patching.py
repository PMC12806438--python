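"""Delay-embed a window into its Hankel image and slice it into patch tokens.

Shows the core data transformation: a length-W window becomes an
L x (W - L + 1) Hankel matrix (each column is a delay vector, anti-diagonals
are constant), which is tiled into p2 x p1 patches that the encoder consumes
as tokens.  Both maps invert exactly.
"""

import numpy as np

from delayformer import HankelImage, PatchSpec, dehankelize, hankelize, patchify, unpatchify

w = np.arange(1.0, 11.0)  # a length-10 window
img = hankelize(w, L=4)
print("window:", w)
print("Hankel image (L=4, C=7):")
print(img.matrix)
print("anti-diagonals constant:", img.is_hankel())

spec = PatchSpec(p1=7, p2=2)  # 7 columns x 2 rows per tile -> 2 tokens
tokens = patchify(img, spec)
print(f"patched into {tokens.shape[0]} tokens of {tokens.shape[1]} values each")

back = unpatchify(tokens, spec, img.L, img.C)
print("unpatchify exact:", np.array_equal(back, img.matrix))
print("dehankelize exact:", np.array_equal(dehankelize(img), w))

# the benchmark geometry: 96-step window, L=49 -> 49x48 image, (6,7) patches
big = hankelize(np.random.default_rng(0).normal(size=96), L=49)
big_tokens = patchify(big, PatchSpec(6, 7))
print(f"benchmark geometry: {big.L}x{big.C} image -> {big_tokens.shape[0]} tokens "
      f"of {big_tokens.shape[1]} values (the encoder's input sequence)")

# anti-diagonal averaging tolerates slightly inconsistent images
perturbed = HankelImage(np.array([[0.0, 2.0], [0.0, 0.0]]))
print("averaged inverse of a non-Hankel image:", dehankelize(perturbed))
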