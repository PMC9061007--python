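"""Object-specific pooling: fixed-length descriptors from any-size maps.

The transverse path pools its feature maps through a 3-level spatial
pyramid (1x1 + 2x2 + 3x3 = 14 bins per channel); the longitudinal path
uses 3-level strip pooling (1 + 2 + 3 = 6 full-width strips per channel).
Descriptor length depends only on the channel count k, never on the input
size.
"""

import numpy as np

from osfpnet import BackboneConfig, PoolingSpec, build_backbone, extract, pool

spp = PoolingSpec.spp_default()
msp = PoolingSpec.msp_default()
print(f"SPP levels {spp.levels} -> {spp.total_units} bins per channel")
print(f"MSP levels {msp.levels} -> {msp.total_units} strips per channel")

fe = build_backbone(BackboneConfig.tiny(), seed=0)  # k = 64 channels
rng = np.random.default_rng(0)
for h, w, spec in [(64, 64, spp), (96, 80, spp), (48, 160, msp), (64, 240, msp)]:
    img = rng.integers(0, 256, (h, w), dtype=np.uint8)
    fmap = extract(fe, img)
    desc = pool(fmap, spec)
    print(f"  input {h}x{w} -> feature map {fmap.k}x{fmap.h}x{fmap.w} "
          f"-> {spec.kind} descriptor of length {desc.values.shape[0]}")
# Same-kind descriptors have identical length for every input size: that is
# what lets four arbitrarily sized views feed one fixed-width classifier.
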