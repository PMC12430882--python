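"""The synthetic acquisition campaign.

Lists the LED bank and the 16 lighting conditions, then generates a small
paired dataset and summarises its manifest.
"""

import collections

from specrec import (SceneParams, build_dataset, builtin_conditions,
                     builtin_led_bank)

bank = builtin_led_bank()
kinds = collections.Counter(led.kind for led in bank)
print(f"LED bank: {len(bank)} LEDs — {dict(kinds)}")

conditions = builtin_conditions()
sizes = collections.Counter(len(c.members) for c in conditions)
print(f"lighting conditions: {len(conditions)} "
      f"(by LED count: {dict(sorted(sizes.items()))})")

params = SceneParams(image_size=32, n_bands=16)
pairs, manifest = build_dataset(32, params=params, seed=11)
splits = collections.Counter(record["split"] for record in manifest)
print(f"dataset: {len(pairs)} five-component pairs, splits {dict(splits)}")

pair = pairs[0]
print(f"first pair: condition={pair.condition.name}, "
      f"object RGB {pair.sample_rgb.values.shape}, "
      f"object cube {pair.sample_hsi.values.shape}, "
      f"reflectance ground truth {pair.reflectance_gt.values.shape}")
pair.validate()
print("record consistency check passed: the stored reflectance equals the "
      "object/light cube ratio.")
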