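"""Dataset split and seven-variant training-set augmentation.

Splits a 121-image collection 70/10/20 with round-half-up counting, then
builds the seven-variant augmentation set for one synthetic image/mask pair.
The printed sizes show why augmentation turns 121 images into 631: the 85
training pairs each gain six transformed variants while validation and
testing stay untouched (85 * 7 + 12 + 24 = 631).
"""

from foodpix.augment import AugmentConfig, augment_pair, augmented_size
from foodpix.imageset import split_dataset
from foodpix.synthetic import SceneSpec, generate_scene, toy_registry

pairs = [(f"img{i:03d}.png", f"img{i:03d}_mask.png") for i in range(121)]
manifest = split_dataset(pairs, seed=1)
n_train, n_val, n_test = manifest.sizes()
print(f"split of 121 pairs: training={n_train} validation={n_val} testing={n_test}")
print(f"augmented dataset size: {augmented_size(n_train, n_val, n_test)}")

registry = toy_registry(56)
image, mask = generate_scene(SceneSpec(seed=1), registry)
variants = augment_pair(image, mask, AugmentConfig(noise_sigma=10.0), seed=1)
print(f"\nvariants of one 500x375 training pair ({len(variants)} total):")
for name, (img_v, msk_v) in variants.items():
    h, w = msk_v.shape
    print(f"  {name:6s} -> {w}x{h}")
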