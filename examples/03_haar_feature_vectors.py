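"""Encode an image as a multi-scale Haar feature vector.

Shows the feature family's structure — how many coefficients each dyadic
scale contributes on a 128x128 image — and verifies the constant-time
integral-image evaluation against a direct dot product for one feature.
"""

import numpy as np

import eustrack as et
from eustrack.haar import eval_haar_feature

rng = np.random.default_rng(0)
img = et.GrayImage(rng.random((128, 128)) * 255, (1.0, 1.0))

basis = et.HaarBasisSet()  # 8 templates, scales 0-3, supports 8-64 px
vec = et.extract_feature_vector(img, basis)
print(f"feature vector length: {len(vec)}")
for start, stop, scale in vec.scale_blocks:
    print(f"  scale {scale} (support {basis.support(scale):3d} px): "
          f"{stop - start:4d} coefficients")

idx = vec.index_map[100]
ii = et.integral_image(img)
print(f"feature 100 ({basis.templates[idx.template_id].name}, "
      f"scale {idx.scale}, t={idx.translation}): "
      f"fast = {eval_haar_feature(ii, idx, basis):.3f}, "
      f"stored = {vec.values[100]:.3f}")
print("identical images correlate at",
      et.match_score(vec, vec)[0])
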